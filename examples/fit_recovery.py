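"""Calibration sanity check: recover a known co-ageing constant.

Generates a hazard-curve target with the simulator at a known C_A, then fits
C_A back from an independent seed using the grid + Nelder-Mead search under
common random numbers.  Scaled down (small cohorts) so it runs in about a
minute; the package's acceptance suite runs the full-size version.
"""

from coageing import FitSpec, fit
from coageing.config import reference_config, run_cohort
from coageing.demography import demography_from_result

SEED = 3
TRUTH = 0.015

target_cfg = reference_config(cohort_size=1500, master_seed=SEED + 1000,
                              topology_mode="shared", max_steps=2000)
target = demography_from_result(run_cohort(target_cfg, record_trajectories=False), 0)
print(f"target: simulated cohort of 1500 with true C_A = {TRUTH}")

# the fit varies dynamics only: evaluations reuse the target's topology seed
# (the network is part of the model being calibrated, not of the noise)
spec = FitSpec(
    base=target_cfg.replace(master_seed=SEED, topology_seed=SEED + 1000),
    free={"a.C": (0.005, 0.03)},
    target=target,
    cohort_size=800,
    max_steps=700,
)
result = fit(spec, master_seed=SEED, grid_points=5, nm_maxiter=8)

rel = abs(result.params["a.C"] - TRUTH) / TRUTH
print(f"recovered C_A = {result.params['a.C']:.5f} "
      f"({rel:.0%} from truth, loss {result.loss:.4g}, {len(result.log)} evaluations)")
print("\nevaluation log (first grid stage):")
grid = result.log[result.log["stage"] == "grid"]
for _, row in grid.iterrows():
    print(f"  C_A = {row['a.C']:.4f}  loss = {row['loss']:.4g}")
print(
    "\nThe loss is deterministic given the seed (common random numbers), so\n"
    "the derivative-free search sees a smooth landscape despite Monte-Carlo\n"
    "simulation inside every evaluation."
)
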