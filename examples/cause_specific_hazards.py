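"""Competing risks: cause-specific hazards and the antibiotic protocol.

Every simulated death carries a cause — intrinsic damage or co-ageing
damage — so the all-cause hazard decomposes exactly into two cause-specific
curves, mirroring necropsy-resolved host/pathogen survival experiments.
Treating the infection is modelled by turning down one number: the
co-ageing constant of the focal species (0.023 untreated -> 0.013 treated),
with every other parameter untouched.
"""

import numpy as np

from coageing import demography_from_result
from coageing.calibration import set_param
from coageing.config import reference_config, run_cohort

SEED = 7
COHORT = 1000

base = reference_config(cohort_size=COHORT, master_seed=SEED)
untreated = set_param(base, "a.C", 0.023)
treated = set_param(base, "a.C", 0.013)

res_u = run_cohort(untreated, record_trajectories=False)
df = demography_from_result(res_u, 0)
ok = df["S"] > 0
assert np.array_equal((df["mu_s"] + df["mu_c"])[ok].to_numpy(), df["mu"][ok].to_numpy())
print("additivity holds exactly: mu_s(t) + mu_c(t) == mu(t) at every step\n")

peak_c = int(df["mu_c"].fillna(0).idxmax())
print(f"untreated cohort (C_A = 0.023):")
print(f"  co-ageing hazard peaks at t = {peak_c} "
      f"(mu_c = {df['mu_c'].iloc[peak_c]:.4f}) — early-life infection deaths")
causes = res_u.death_causes[0]
print(f"  deaths: {int((causes == 2).sum())} co-ageing, {int((causes == 1).sum())} intrinsic")

res_t = run_cohort(treated, record_trajectories=False)
causes_t = res_t.death_causes[0]
print(f"\ntreated cohort (C_A = 0.013, all else identical):")
print(f"  deaths: {int((causes_t == 2).sum())} co-ageing, {int((causes_t == 1).sum())} intrinsic")
print(f"  mean lifespan {res_t.mean_lifespan(0):.1f} vs {res_u.mean_lifespan(0):.1f} untreated")

print(
    "\nLowering the single antagonist-damage constant shifts deaths from the\n"
    "co-ageing column to the intrinsic column and extends life — the model's\n"
    "account of an antibiotic intervention."
)
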