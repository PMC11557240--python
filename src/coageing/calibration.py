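"""Parameter sweeps and simulation-based fitting to empirical hazard curves.

The model defines no likelihood, so fitting is simulation-based: each
candidate parameter set is run as a full cohort with *common random numbers*
(the same master seed for every evaluation), which makes the loss a
deterministic function of the parameters and lets a derivative-free search
(coarse grid, then Nelder–Mead refinement within bounds) operate on
Monte-Carlo output.  The loss is a weighted sum of squared hazard
differences, weighted by the simulated survivor fraction S(t)/max S, because
the binomial variance of a hazard estimate scales as 1/S(t).

Free parameters are addressed as ``"a.C"``, ``"b.d"``, ... — species block
letter, dot, :class:`~coageing.engine.SpeciesParams` field.  Target tables
carry a time column ``t`` plus any of ``mu`` (all-cause), ``mu_s``
(intrinsic) and ``mu_c`` (co-ageing); cause-specific targets are fitted
simultaneously, their sum being the all-cause curve by construction.  A
``time_scale`` (simulation steps per data time unit) aligns the two clocks.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .config import RunConfig, run_cohort
from .demography import demography_from_result
from .engine import CohortResult

__all__ = ["FitSpec", "FitResult", "SweepPoint", "sweep", "fit", "paired_condition_fit",
           "set_param", "evaluate_loss"]

_TARGET_COLUMNS = ("mu", "mu_s", "mu_c")


def set_param(config: RunConfig, name: str, value: float) -> RunConfig:
    """Return a config with one species parameter replaced (``"a.C"`` style)."""
    block, _, fname = name.partition(".")
    if block not in ("a", "b") or not fname:
        raise ValueError(f"parameter name {name!r} must look like 'a.C' or 'b.d'")
    attr = "species_a" if block == "a" else "species_b"
    species = getattr(config, attr)
    if species is None:
        raise ValueError(f"config has no species block {block!r}")
    if fname not in {f.name for f in dataclasses.fields(species)}:
        raise ValueError(f"unknown species parameter {fname!r}")
    if fname == "n_nodes":
        value = int(round(value))
    return config.replace(**{attr: dataclasses.replace(species, **{fname: value})})


@dataclass
class SweepPoint:
    value: float
    demography: pd.DataFrame
    mean_lifespan: float
    result: CohortResult


def sweep(
    base_config: RunConfig,
    parameter: str,
    values: Sequence[float],
    cohort_size: Optional[int] = None,
    master_seed: Optional[int] = None,
    species: int = 0,
) -> list[SweepPoint]:
    """One cohort demography per parameter value, under common random numbers.

    Every value is simulated with the same master seed (variance reduction:
    differences between sweep points reflect the parameter, not fresh
    Monte-Carlo noise).  Deterministic given the seed.
    """
    config = base_config
    if cohort_size is not None:
        config = config.replace(cohort_size=cohort_size)
    if master_seed is not None:
        config = config.replace(master_seed=master_seed)
    points = []
    for value in values:
        cfg = set_param(config, parameter, value)
        result = run_cohort(cfg, record_trajectories=False)
        points.append(
            SweepPoint(
                value=float(value),
                demography=demography_from_result(result, species=species),
                mean_lifespan=result.mean_lifespan(species),
                result=result,
            )
        )
    return points


@dataclass
class FitSpec:
    """Everything a fit needs.

    ``free`` maps parameter names to (low, high) bounds; all other model
    parameters stay frozen at their ``base`` values.  ``target`` is a table
    with column ``t`` and at least one of ``mu``, ``mu_s``, ``mu_c`` for the
    fitted ``species`` (0 = A, 1 = B).
    """

    base: RunConfig
    free: dict[str, tuple[float, float]]
    target: pd.DataFrame
    species: int = 0
    time_scale: float = 1.0
    cohort_size: Optional[int] = None
    max_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        if self.target is None or len(self.target) == 0:
            raise ValueError("fit target is empty")
        if "t" not in self.target.columns:
            raise ValueError("target needs a 't' column")
        if not any(c in self.target.columns for c in _TARGET_COLUMNS):
            raise ValueError(f"target needs one of {_TARGET_COLUMNS}")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")
        for name, (lo, hi) in self.free.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy low < high")

    def _config(self, values: dict[str, float]) -> RunConfig:
        config = self.base
        if self.cohort_size is not None:
            config = config.replace(cohort_size=self.cohort_size)
        if self.max_steps is not None:
            config = config.replace(max_steps=self.max_steps)
        for name, value in values.items():
            config = set_param(config, name, value)
        return config


def _target_loss(spec: FitSpec, demog: pd.DataFrame) -> float:
    t_data = spec.target["t"].to_numpy(dtype=float)
    t_sim = np.rint(t_data * spec.time_scale).astype(int)
    in_range = (t_sim >= 0) & (t_sim <= int(demog["t"].iloc[-1]))
    if not in_range.any():
        raise ValueError("target and simulation time ranges are disjoint after alignment")
    s = demog["S"].to_numpy(dtype=float)
    weights = s / s.max()
    loss = 0.0
    for col in _TARGET_COLUMNS:
        if col not in spec.target.columns:
            continue
        y = spec.target[col].to_numpy(dtype=float)
        yhat = np.full_like(y, np.nan)
        yhat[in_range] = demog[col].to_numpy(dtype=float)[t_sim[in_range]]
        w = np.zeros_like(y)
        w[in_range] = weights[t_sim[in_range]]
        ok = np.isfinite(y) & np.isfinite(yhat)
        loss += float(np.sum(w[ok] * (y[ok] - yhat[ok]) ** 2))
    return loss


def evaluate_loss(spec: FitSpec, values: dict[str, float], master_seed: int) -> float:
    """Loss of one parameter set under common random numbers."""
    config = spec._config(values).replace(master_seed=master_seed)
    result = run_cohort(config, record_trajectories=False)
    demog = demography_from_result(result, species=spec.species)
    return _target_loss(spec, demog)


@dataclass
class FitResult:
    params: dict[str, float]
    loss: float
    log: pd.DataFrame  # one row per evaluation: parameters + loss + stage

    def __repr__(self) -> str:  # compact: the log can be long
        ps = ", ".join(f"{k}={v:.5g}" for k, v in self.params.items())
        return f"FitResult({ps}, loss={self.loss:.4g}, {len(self.log)} evaluations)"


def _grid_axes(free: dict[str, tuple[float, float]], grid_points: int) -> list[np.ndarray]:
    k = len(free)
    per_axis = grid_points if k == 1 else max(3, int(round(64 ** (1.0 / k))))
    return [np.linspace(lo, hi, per_axis) for lo, hi in free.values()]


def fit(
    spec: FitSpec,
    master_seed: int = 0,
    grid_points: int = 7,
    refine: bool = True,
    nm_maxiter: int = 40,
) -> FitResult:
    """Minimize the hazard-curve loss over the free parameters.

    Stage one evaluates a coarse grid over the bounds; stage two refines the
    best grid point with bounded Nelder–Mead.  Common random numbers make
    every evaluation (hence the whole fit) deterministic given
    ``master_seed``.  Returns the best parameters, their loss, and the full
    evaluation log.
    """
    names = list(spec.free)
    log_rows: list[dict] = []

    def objective(vec: np.ndarray, stage: str) -> float:
        values = {n: float(v) for n, v in zip(names, vec)}
        loss = evaluate_loss(spec, values, master_seed)
        log_rows.append({**values, "loss": loss, "stage": stage})
        return loss

    best_vec, best_loss = None, np.inf
    for combo in itertools.product(*_grid_axes(spec.free, grid_points)):
        loss = objective(np.asarray(combo), "grid")
        if loss < best_loss:
            best_vec, best_loss = np.asarray(combo), loss

    if refine:
        bounds = list(spec.free.values())
        res = optimize.minimize(
            objective,
            best_vec,
            args=("simplex",),
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": nm_maxiter, "xatol": 1e-4, "fatol": 1e-12},
        )
        if res.fun < best_loss:
            best_vec, best_loss = np.asarray(res.x), float(res.fun)

    params = {n: float(v) for n, v in zip(names, best_vec)}
    return FitResult(params=params, loss=float(best_loss), log=pd.DataFrame(log_rows))


def paired_condition_fit(
    base: RunConfig,
    targets: Sequence[pd.DataFrame],
    shared: dict[str, tuple[float, float]],
    per_condition: dict[str, tuple[float, float]],
    master_seed: int = 0,
    species: int = 0,
    time_scale: float = 1.0,
    cohort_size: Optional[int] = None,
    grid_points: int = 5,
    refine: bool = True,
    nm_maxiter: int = 60,
) -> dict:
    """Joint fit across experimental conditions.

    ``shared`` parameters take a single value for every condition;
    ``per_condition`` parameters take one value per target (the protocol used
    for antibiotic treatment — one co-ageing constant per condition, all else
    shared — and for chess expected-outcome bands).  The loss is the sum of
    the per-condition losses, each under common random numbers.

    Returns ``{"shared": {...}, "conditions": [{...}, ...], "loss": float,
    "log": DataFrame}``.
    """
    if len(targets) < 2:
        raise ValueError("paired_condition_fit needs at least two conditions")
    if not shared and not per_condition:
        raise ValueError("at least one free parameter is required")
    if set(shared) & set(per_condition):
        raise ValueError("shared and per-condition parameter sets must be disjoint")

    specs = [
        FitSpec(
            base=base,
            free={**shared, **per_condition} or {"a.C": (0.0, 1.0)},
            target=target,
            species=species,
            time_scale=time_scale,
            cohort_size=cohort_size,
        )
        for target in targets
    ]
    shared_names = list(shared)
    per_names = list(per_condition)
    n_cond = len(targets)
    names = shared_names + [
        f"{name}[{c}]" for c in range(n_cond) for name in per_names
    ]
    bounds = list(shared.values()) + [per_condition[n] for _ in range(n_cond) for n in per_names]
    log_rows: list[dict] = []

    def split(vec: np.ndarray) -> list[dict[str, float]]:
        shared_vals = {n: float(v) for n, v in zip(shared_names, vec[: len(shared_names)])}
        out = []
        k = len(shared_names)
        for _ in range(n_cond):
            cond = dict(shared_vals)
            for name in per_names:
                cond[name] = float(vec[k])
                k += 1
            out.append(cond)
        return out

    def objective(vec: np.ndarray, stage: str) -> float:
        loss = 0.0
        for spec_c, values in zip(specs, split(vec)):
            loss += evaluate_loss(spec_c, values, master_seed)
        log_rows.append({**dict(zip(names, map(float, vec))), "loss": loss, "stage": stage})
        return loss

    axes = [np.linspace(lo, hi, max(3, grid_points) if len(bounds) == 1 else 3)
            for lo, hi in bounds]
    # cap the factorial grid; fall back to seeded random starts when too big
    n_grid = int(np.prod([len(a) for a in axes]))
    if n_grid <= 81:
        candidates = itertools.product(*axes)
    else:
        rng = np.random.default_rng(master_seed)
        lows = np.array([b[0] for b in bounds])
        highs = np.array([b[1] for b in bounds])
        candidates = [lows + rng.random(len(bounds)) * (highs - lows) for _ in range(64)]
    best_vec, best_loss = None, np.inf
    for combo in candidates:
        vec = np.asarray(list(combo), dtype=float)
        loss = objective(vec, "grid")
        if loss < best_loss:
            best_vec, best_loss = vec, loss

    if refine:
        res = optimize.minimize(
            objective,
            best_vec,
            args=("simplex",),
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": nm_maxiter, "xatol": 1e-4, "fatol": 1e-12},
        )
        if res.fun < best_loss:
            best_vec, best_loss = np.asarray(res.x), float(res.fun)

    conds = split(best_vec)
    shared_out = {n: float(v) for n, v in zip(shared_names, best_vec[: len(shared_names)])}
    return {
        "shared": shared_out,
        "conditions": conds,
        "loss": float(best_loss),
        "log": pd.DataFrame(log_rows),
    }
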