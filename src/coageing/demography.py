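"""Cohort demography: survival counts, hazards, interval mortality.

Time is discrete (simulation steps or chess turns).  ``S(t)`` counts the
individuals at risk at step ``t`` — everyone whose death time is >= t plus
all censored-alive individuals (simulation survivors, chess winners), who
remain in ``S`` forever and never enter a death numerator.  With deaths
``d(t)`` at step ``t``:

    mu(t)   = [S(t) - S(t+1)] / S(t) = d(t) / S(t)          (all-cause)
    mu_i(t) = d_i(t) / S(t)                                  (cause-specific)

Deaths by intrinsic and co-ageing damage are mutually exclusive competing
events, so the all-cause hazard is exactly the sum of the two cause-specific
hazards.  Steps with ``S(t) = 0`` have undefined hazards and are reported as
NaN, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import CAUSE_COAGEING, CAUSE_INTRINSIC, CohortResult

__all__ = [
    "hazard_curve",
    "cause_specific_hazards",
    "cohort_demography",
    "demography_from_result",
    "restricted_mean_lifespan",
    "interval_mortality",
    "smooth_hazard",
    "detect_bump",
    "BumpReport",
    "write_hazard_table",
    "read_hazard_table",
]

HAZARD_COLUMNS = ["t", "S", "d_s", "d_c", "mu", "mu_s", "mu_c"]


def _death_counts(death_times: np.ndarray, max_t: Optional[int]) -> tuple[np.ndarray, int, int]:
    dt = np.asarray(death_times, dtype=np.int64)
    if dt.size == 0:
        raise ValueError("empty cohort")
    dead = dt >= 0
    if max_t is None:
        max_t = int(dt[dead].max()) if dead.any() else 0
    counts = np.bincount(dt[dead & (dt <= max_t)], minlength=max_t + 1)
    return counts, max_t, int(dt.size)


def hazard_curve(
    death_times: Sequence[int] | np.ndarray, max_t: Optional[int] = None
) -> pd.DataFrame:
    """All-cause survival and hazard from death times.

    ``death_times`` holds the step each individual died; censored individuals
    carry -1 and stay in the risk set forever.  Returns a frame with columns
    ``t, S, d, mu`` for t = 0..max_t (default: the last observed death).
    """
    counts, max_t, n = _death_counts(death_times, max_t)
    s = np.empty(max_t + 1, dtype=np.int64)
    s[0] = n
    if max_t > 0:
        s[1:] = n - np.cumsum(counts[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(s > 0, counts / np.where(s > 0, s, 1), np.nan)
    return pd.DataFrame({"t": np.arange(max_t + 1), "S": s, "d": counts, "mu": mu})


def cause_specific_hazards(
    death_times: Sequence[int] | np.ndarray,
    death_causes: Sequence[int] | np.ndarray,
    max_t: Optional[int] = None,
) -> pd.DataFrame:
    """Competing-risks decomposition of the hazard.

    ``death_causes`` uses the engine's codes (1 intrinsic, 2 co-ageing,
    0 censored).  Returns columns ``t, S, d_s, d_c, mu, mu_s, mu_c``; by
    construction ``mu_s + mu_c == mu`` exactly wherever S > 0.
    """
    dt = np.asarray(death_times, dtype=np.int64)
    causes = np.asarray(death_causes, dtype=np.int64)
    if dt.shape != causes.shape:
        raise ValueError("death_times and death_causes must align")
    dead = dt >= 0
    known = {0, CAUSE_INTRINSIC, CAUSE_COAGEING}
    if not set(np.unique(causes)).issubset(known):
        raise ValueError("unknown cause label in death_causes")
    if np.any(causes[dead] == 0):
        raise ValueError("every death must carry exactly one cause")
    base = hazard_curve(dt, max_t)
    max_t = int(base["t"].iloc[-1])
    d_s = np.bincount(dt[dead & (causes == CAUSE_INTRINSIC) & (dt <= max_t)], minlength=max_t + 1)
    d_c = np.bincount(dt[dead & (causes == CAUSE_COAGEING) & (dt <= max_t)], minlength=max_t + 1)
    s = base["S"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(s > 0, s, 1)
        mu_s = np.where(s > 0, d_s / safe, np.nan)
        mu_c = np.where(s > 0, d_c / safe, np.nan)
    # the all-cause hazard is the SUM of the cause-specific hazards; summing
    # the rounded quotients keeps that identity exact in floating point too
    return pd.DataFrame(
        {
            "t": base["t"],
            "S": s,
            "d_s": d_s,
            "d_c": d_c,
            "mu": mu_s + mu_c,
            "mu_s": mu_s,
            "mu_c": mu_c,
        }
    )


# Back-compatible alias: the full seven-column table IS the cohort demography.
cohort_demography = cause_specific_hazards


def demography_from_result(result: CohortResult, species: int = 0,
                           max_t: Optional[int] = None) -> pd.DataFrame:
    """Hazard table for one species of a simulated cohort."""
    dt, causes = result.death_records(species)
    return cause_specific_hazards(dt, causes, max_t)


def restricted_mean_lifespan(
    death_times: Sequence[int] | np.ndarray, horizon: int
) -> float:
    """Restricted mean survival time E[min(T, horizon)].

    Unlike the mean of uncensored death times, this statistic is monotone
    under stochastic ordering even when part of the cohort outlives the
    observation window (censored individuals count as surviving to the
    horizon), which makes it the right comparator for parameter-trend
    studies with long-lived regimes.
    """
    dt = np.asarray(death_times, dtype=np.int64)
    if dt.size == 0:
        raise ValueError("empty cohort")
    clipped = np.where(dt < 0, horizon, np.minimum(dt, horizon))
    return float(clipped.mean())


def interval_mortality(s_ti: float, s_tf: float, delta_t: float) -> float:
    """Annualized interval mortality ``1 - (S(tf)/S(ti))**(1/dt)``.

    The standard forest-census formula for a survivor count that dropped from
    ``s_ti`` to ``s_tf`` over ``delta_t`` time units; with ``delta_t = 1`` it
    reduces exactly to the discrete hazard ``[S(t) - S(t+1)] / S(t)``.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if s_tf > s_ti:
        raise ValueError("survivors cannot increase over an interval")
    if s_tf <= 0 or s_ti <= 0:
        raise ValueError("survivor counts must be positive")
    if delta_t == 1:
        # algebraically the same, but exact in floating point too
        return (s_ti - s_tf) / s_ti
    return 1.0 - (s_tf / s_ti) ** (1.0 / delta_t)


def smooth_hazard(mu: Sequence[float] | np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated end windows.

    ``window`` must be odd; ``window=1`` is the identity.  NaN entries are
    treated as missing: they do not poison their neighbours and remain NaN
    only where the whole window is undefined.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(mu, dtype=float)
    if window == 1:
        return x.copy()
    valid = np.isfinite(x)
    filled = np.where(valid, x, 0.0)
    kernel = np.ones(window)
    totals = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, totals / counts, np.nan)
    return out


@dataclass
class BumpReport:
    """Interior extrema of a (smoothed) hazard series.

    A *bump* — the co-ageing signature — is a local maximum followed by a
    local minimum: the hazard rises, falls back as the antagonists perish,
    then resumes its late-life rise.
    """

    maxima: list[int]
    minima: list[int]
    bumps: list[tuple[int, int]]

    @property
    def has_bump(self) -> bool:
        return len(self.bumps) > 0


def detect_bump(
    mu: Sequence[float] | np.ndarray,
    window: int = 1,
    min_drop: float = 0.0,
) -> BumpReport:
    """Find interior local extrema of the smoothed hazard and report bumps.

    The series is smoothed with :func:`smooth_hazard`, plateaus are collapsed,
    and strict sign changes of the first difference give the extrema (a
    monotone or constant series yields none).  A (max, min) pair only counts
    as a bump when the hazard drops by more than ``min_drop`` between them —
    on Monte-Carlo estimates set ``min_drop`` to a few binomial standard
    errors to suppress noise-level wiggles.
    """
    x = np.asarray(mu, dtype=float)
    if x.size < 3:
        raise ValueError("series too short for extremum detection")
    sm = smooth_hazard(x, window)
    idx = np.flatnonzero(np.isfinite(sm))
    vals = sm[idx]
    # collapse plateaus to their first index
    keep = np.concatenate(([True], np.diff(vals) != 0))
    idx, vals = idx[keep], vals[keep]
    maxima: list[int] = []
    minima: list[int] = []
    for k in range(1, len(vals) - 1):
        if vals[k] > vals[k - 1] and vals[k] > vals[k + 1]:
            maxima.append(int(idx[k]))
        elif vals[k] < vals[k - 1] and vals[k] < vals[k + 1]:
            minima.append(int(idx[k]))
    bumps: list[tuple[int, int]] = []
    for mx in maxima:
        following = [mn for mn in minima if mn > mx]
        if not following:
            continue
        mn = following[0]
        if sm[mx] - sm[mn] > min_drop:
            bumps.append((mx, mn))
    return BumpReport(maxima, minima, bumps)


def write_hazard_table(df: pd.DataFrame, path) -> None:
    """Write a hazard table as plain TSV (NaN rendered as empty)."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_hazard_table(path) -> pd.DataFrame:
    """Read a hazard (or calibration-target) TSV written by this package."""
    return pd.read_csv(path, sep="\t")
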