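"""How each model parameter bends the hazard curve.

Sweeps the focal species' co-ageing constant, intrinsic damage rate, repair
rate and initial functional fraction — and the antagonist's co-ageing
constant — under common random numbers, reporting restricted mean lifespans
(robust to censoring) and the size of the co-ageing bump.
"""

import math

import numpy as np

from coageing import detect_bump, restricted_mean_lifespan, smooth_hazard
from coageing.calibration import sweep
from coageing.config import reference_config

SEED = 11
HORIZON = 3000
base = reference_config(cohort_size=800, master_seed=SEED,
                        topology_mode="shared", max_steps=HORIZON)


def rmst(point):
    return restricted_mean_lifespan(point.result.death_times[0], HORIZON)


def bump_drop(point):
    df = point.demography
    mu, s = df["mu"].to_numpy(), df["S"].to_numpy()
    lim = int(np.argmax(s < 100)) if (s < 100).any() else len(s)
    sm = smooth_hazard(mu[:lim], 31)
    best = 0.0
    for mx, mn in detect_bump(mu[:lim], 31).bumps:
        se = math.sqrt(max(sm[mx], 1e-12) * (1 - sm[mx]) / s[mx])
        if sm[mx] - sm[mn] > 3 * se:
            best = max(best, sm[mx] - sm[mn])
    return best


print("parameter sweeps, restricted mean lifespan of species A (steps):\n")
for name, values, meaning in [
    ("a.C", [0.005, 0.015, 0.03], "damage received from antagonist (shortens life)"),
    ("a.d", [0.002, 0.004, 0.008], "intrinsic per-step damage (shortens life)"),
    ("a.r", [0.0, 0.02, 0.04], "repair probability (extends life)"),
    ("a.f0", [0.8, 0.9, 1.0], "initial functional fraction (extends life)"),
]:
    points = sweep(base, name, values)
    span = ", ".join(f"{p.value:g}: {rmst(p):7.1f}" for p in points)
    print(f"  {name:5} -> {span}   [{meaning}]")

print("\nantagonist frailty and the bump (cohort 2000 for a stable estimate):")
points = sweep(base.replace(cohort_size=2000), "b.C", [0.005, 0.015, 0.04])
for p in points:
    print(f"  C_B = {p.value:5.3f}: bump drop {bump_drop(p):.4f}  "
          f"(tau_B = {p.result.mean_lifespan(1):6.1f})")
print(
    "\nRaising C_B kills the antagonist earlier, shrinking the co-ageing era\n"
    "of A: the bump shrinks and finally vanishes."
)
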