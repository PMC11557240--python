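"""Solo ageing versus co-ageing: the hazard-curve bump.

Simulates the reference cohort twice — once with the focal species A coupled
to its frailer antagonist B (C_A = 0.015), once uncoupled (C_A = 0) — and
shows that the coupling carves a transient bump into A's hazard curve whose
declining flank brackets tau_B, the antagonist's mean lifespan.  A bump like
this in empirical demographic data is the model's signature of co-ageing.
"""

import math

import numpy as np

from coageing import demography_from_result, detect_bump, smooth_hazard
from coageing.config import reference_config, run_cohort

SEED = 42
COHORT = 2000  # the 3-standard-error bump filter needs a well-populated cohort

co = run_cohort(reference_config(cohort_size=COHORT, master_seed=SEED),
                record_trajectories=False)
solo = run_cohort(reference_config(coageing=False, cohort_size=COHORT, master_seed=SEED),
                  record_trajectories=False)

tau_a, tau_b = co.mean_lifespan(0), co.mean_lifespan(1)
print(f"mean lifespan of A while co-ageing : {tau_a:7.1f} steps")
print(f"mean lifespan of A ageing solo     : {solo.mean_lifespan(0):7.1f} steps")
print(f"mean lifespan of the antagonist B  : {tau_b:7.1f} steps (tau_B)")

for label, res in (("co-ageing", co), ("solo", solo)):
    df = demography_from_result(res, 0)
    mu, s = df["mu"].to_numpy(), df["S"].to_numpy()
    lim = int(np.argmax(s < 100)) if (s < 100).any() else len(s)
    sm = smooth_hazard(mu[:lim], 31)
    bumps = []
    for mx, mn in detect_bump(mu[:lim], 31).bumps:
        se = math.sqrt(max(sm[mx], 1e-12) * (1 - sm[mx]) / s[mx])
        if sm[mx] - sm[mn] > 3 * se:
            bumps.append((mx, mn))
    print(f"{label:>10}: significant hazard bumps at {bumps or 'none'}")

print(
    "\nThe co-ageing curve rises while B is alive, dips as the antagonists\n"
    "perish around tau_B, then resumes its intrinsic late-life rise; the\n"
    "uncoupled control shows no such bump."
)
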