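"""Two-round damage / propagation / repair dynamics for co-ageing network pairs.

Each time step, species A undergoes two damage rounds followed by its
antagonist B:

* round one — every functional node is marked dysfunctional with the
  intrinsic per-step rate ``d``; the damage is then propagated: any
  functional node that has lost strictly more than half of its dependees
  fails too, iterated to a fixed point;
* round two — functional nodes are marked with the antagonist-driven rate
  ``alpha = C * f_opponent / N_opponent`` (the co-ageing coupling), and the
  damage is propagated the same way.

After each round every dysfunctional node reverts to functional with the
repair probability ``r``.  Every dysfunctional node carries a cause tag
(intrinsic or co-ageing): directly marked nodes take the round they were
marked in, propagated nodes inherit the majority cause among their
dysfunctional dependees (exact ties resolve to intrinsic).  A network dies
when its functional fraction first drops strictly below the threshold
``phi_T``; the cause of death is intrinsic if at that moment more nodes are
down from intrinsic damage than from co-ageing damage, co-ageing otherwise
(ties to intrinsic).  Dead networks are frozen and inflict no further
co-ageing damage.

The cohort simulator vectorizes all pairs at once and compacts its working
arrays as individuals die, so late-life tails cost only the survivors.
Randomness comes from counter-based (Philox) generators keyed by
(master seed, species slot, time step, purpose): a species' draws do not
depend on whether an antagonist is present, so setting ``C = 0`` reproduces
a solo-ageing run bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .network import DependencyNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesParams",
    "SpeciesTrajectory",
    "PairTrajectory",
    "CohortResult",
    "apply_prenatal_damage",
    "propagate_damage",
    "label_network_death",
    "simulate_pair",
    "simulate_cohort",
    "simulate_solo_cohort",
    "CAUSE_NONE",
    "CAUSE_INTRINSIC",
    "CAUSE_COAGEING",
]

CAUSE_NONE = 0
CAUSE_INTRINSIC = 1
CAUSE_COAGEING = 2
_CAUSE_NAMES = {CAUSE_INTRINSIC: "intrinsic", CAUSE_COAGEING: "coageing"}

# RNG stream purposes within one (species, step) block
_P_MARK1, _P_REPAIR1, _P_MARK2, _P_REPAIR2, _P_PRENATAL = range(5)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species model parameters.

    Parameters
    ----------
    n_nodes:
        Network size N.
    d:
        Per-step intrinsic marking probability (round one), in [0, 1].
    r:
        Per-round repair probability, in [0, 1].
    C:
        Co-ageing constant: damage *received* from the antagonist scales as
        ``C * f_opponent / N_opponent``.  Non-negative.
    f0:
        Initial functional fraction in (0, 1]; ``1 - f0`` is the prenatal
        damage.
    phi_T:
        Death threshold: the network is dead once its functional fraction is
        strictly below ``phi_T``.  Default 0.10 (0.15 for the chess regime).
    """

    n_nodes: int
    d: float = 0.0
    r: float = 0.0
    C: float = 0.0
    f0: float = 1.0
    phi_T: float = 0.10

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for name in ("d", "r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.C < 0.0:
            raise ValueError(f"C={self.C} must be non-negative")
        if not 0.0 < self.f0 <= 1.0:
            raise ValueError(f"f0={self.f0} outside (0, 1]")
        if not 0.0 < self.phi_T < 1.0:
            raise ValueError(f"phi_T={self.phi_T} outside (0, 1)")
        if self.phi_T >= self.f0:
            raise ValueError("death threshold phi_T must be below f0")


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------


def _stream(master_seed: int, species_slot: int, step: int, purpose: int) -> np.random.Generator:
    """Counter-keyed Philox stream: independent of any iteration order."""
    if step >= 1 << 24 or species_slot >= 1 << 4 or purpose >= 1 << 4:
        raise ValueError("stream key component out of range")
    key = (int(master_seed) << 32) | (species_slot << 28) | (purpose << 24) | step
    return np.random.Generator(np.random.Philox(key=key))


# ---------------------------------------------------------------------------
# Cohort topology: dependee-count queries for the materialized rows
# ---------------------------------------------------------------------------


class _CohortTopology:
    """Answers "how many dependees of each node satisfy a predicate" for the
    currently materialized rows, with one shared topology or one per row."""

    def __init__(self, networks: Sequence[DependencyNetwork], cohort_size: int):
        if len(networks) not in (1, cohort_size):
            raise ValueError("provide one shared network or one per individual")
        self.n_nodes = networks[0].n_nodes
        if any(n.n_nodes != self.n_nodes for n in networks):
            raise ValueError("all cohort topologies must have the same n_nodes")
        self.shared = len(networks) == 1 or all(n is networks[0] for n in networks)
        if self.shared:
            self._m = networks[0].dependee_matrix()  # (N, N)
            self._ndep_row = networks[0].dependee_counts()
            self._mats = None
        else:
            self._mats = [n.dependee_matrix() for n in networks]
            self._m = sp.block_diag(self._mats, format="csr")
            self._ndep = np.stack([n.dependee_counts() for n in networks])

    def ndep(self, n_rows: int) -> np.ndarray:
        if self.shared:
            return np.broadcast_to(self._ndep_row, (n_rows, self.n_nodes))
        return self._ndep

    def counts(self, mask: np.ndarray) -> np.ndarray:
        """mask: (rows, N) bool -> per-node count of True dependees."""
        x = mask.astype(np.int32)
        if self.shared:
            return (self._m @ x.T).T
        flat = self._m @ x.reshape(-1)
        return flat.reshape(x.shape)

    def subset(self, keep: np.ndarray) -> None:
        """Drop rows (individuals) whose mask entry is False."""
        if self.shared:
            return
        self._mats = [m for m, k in zip(self._mats, keep) if k]
        self._m = sp.block_diag(self._mats, format="csr") if self._mats else None
        self._ndep = self._ndep[keep]


# ---------------------------------------------------------------------------
# Elementary operations (vectorized core + single-network wrappers)
# ---------------------------------------------------------------------------


def _prenatal(status: np.ndarray, tag: np.ndarray, f0: float, rng: np.random.Generator) -> None:
    """Knock out exactly round((1-f0)*N) uniformly chosen nodes per row."""
    cohort, n = status.shape
    k = int(round((1.0 - f0) * n))
    if k == 0:
        return
    order = np.argsort(rng.random((cohort, n)), axis=1)[:, :k]
    rows = np.repeat(np.arange(cohort), k)
    status[rows, order.reshape(-1)] = False
    tag[rows, order.reshape(-1)] = CAUSE_INTRINSIC


def apply_prenatal_damage(
    net: DependencyNetwork, f0: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial node states for one network with prenatal damage ``1 - f0``.

    Returns ``(status, tag)`` arrays of length ``n_nodes``: ``status`` is True
    where functional; exactly ``round((1-f0)*N)`` uniformly chosen nodes start
    dysfunctional, tagged intrinsic.
    """
    if not 0.0 < f0 <= 1.0:
        raise ValueError(f"f0={f0} outside (0, 1]")
    status = np.ones((1, net.n_nodes), dtype=bool)
    tag = np.zeros((1, net.n_nodes), dtype=np.uint8)
    _prenatal(status, tag, f0, rng)
    return status[0], tag[0]


def _propagate(topo: _CohortTopology, status: np.ndarray, tag: np.ndarray) -> None:
    """Synchronous-sweep cascade to the fixed point (in place).

    A functional node fails when strictly more than half of its dependees are
    dysfunctional, counting every currently dysfunctional dependee regardless
    of when it failed.  The new failure inherits the majority cause among its
    dysfunctional dependees; an exact tie resolves to intrinsic.
    """
    ndep = topo.ndep(status.shape[0])
    while True:
        dys = ~status
        cd = topo.counts(dys)
        new = status & (2 * cd > ndep)
        if not new.any():
            break
        if (tag == CAUSE_COAGEING).any():
            ci = topo.counts(tag == CAUSE_INTRINSIC)
            cc = cd - ci
            newtag = np.where(ci >= cc, CAUSE_INTRINSIC, CAUSE_COAGEING).astype(np.uint8)
            tag[new] = newtag[new]
        else:
            tag[new] = CAUSE_INTRINSIC
        status[new] = False


def propagate_damage(
    net: DependencyNetwork, status: np.ndarray, tag: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate existing damage through one network to the fixed point.

    Returns updated copies of ``(status, tag)``; idempotent.
    """
    topo = _CohortTopology([net], 1)
    s = np.array(status, dtype=bool).reshape(1, -1).copy()
    t = np.array(tag, dtype=np.uint8).reshape(1, -1).copy()
    _propagate(topo, s, t)
    return s[0], t[0]


def label_network_death(ns: int, nc: int) -> str:
    """Cause of death of a collapsed network.

    Intrinsic if more nodes are down from intrinsic damage than from
    co-ageing damage, co-ageing if the reverse; an exact tie is labelled
    intrinsic (documented tie-break; the model only specifies the strict
    inequalities).
    """
    return "coageing" if nc > ns else "intrinsic"


# ---------------------------------------------------------------------------
# Trajectories and results
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTrajectory:
    """Time series for one network of one pair.

    ``f``, ``ns``, ``nc`` give, per recorded step (0 = after prenatal
    damage), the counts of functional, dysfunctional-by-intrinsic and
    dysfunctional-by-co-ageing nodes; they sum to ``n_nodes`` at every step.
    """

    f: np.ndarray
    ns: np.ndarray
    nc: np.ndarray
    death_time: Optional[int]
    death_cause: str  # "intrinsic" | "coageing" | "censored"

    @property
    def censored(self) -> bool:
        return self.death_time is None


@dataclass
class PairTrajectory:
    a: SpeciesTrajectory
    b: Optional[SpeciesTrajectory] = None


@dataclass
class CohortResult:
    """Vectorized outcome of a cohort run.

    ``death_times[s]`` holds -1 for censored individuals; ``death_causes[s]``
    holds 0 for censored, otherwise the cause code.  Per-species full state
    histories (shape ``(T+1, cohort)``) are kept when trajectories were
    recorded; rows of dead individuals stay frozen at their final state.
    """

    cohort_size: int
    n_species: int
    params: tuple[SpeciesParams, ...]
    death_times: np.ndarray  # (n_species, cohort) int64, -1 = censored
    death_causes: np.ndarray  # (n_species, cohort) uint8, 0 = censored
    n_steps: int
    f: Optional[np.ndarray] = None   # (n_species, T+1, cohort) int16
    ns: Optional[np.ndarray] = None
    nc: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.cohort_size

    def __getitem__(self, pair_id: int) -> PairTrajectory:
        if self.f is None:
            raise ValueError("trajectories were not recorded for this run")
        species = []
        for s in range(self.n_species):
            dt = int(self.death_times[s, pair_id])
            cause = (
                _CAUSE_NAMES[int(self.death_causes[s, pair_id])]
                if dt >= 0
                else "censored"
            )
            species.append(
                SpeciesTrajectory(
                    f=self.f[s, :, pair_id].copy(),
                    ns=self.ns[s, :, pair_id].copy(),
                    nc=self.nc[s, :, pair_id].copy(),
                    death_time=dt if dt >= 0 else None,
                    death_cause=cause,
                )
            )
        return PairTrajectory(species[0], species[1] if self.n_species == 2 else None)

    def trajectories(self) -> list[PairTrajectory]:
        return [self[i] for i in range(self.cohort_size)]

    def mean_lifespan(self, species: int = 0) -> float:
        """Mean death time of uncensored individuals (tau)."""
        dt = self.death_times[species]
        dead = dt >= 0
        if not dead.any():
            return math.nan
        return float(dt[dead].mean())

    def death_records(self, species: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(death_times with -1 for censored, cause codes) for one species."""
        return self.death_times[species].copy(), self.death_causes[species].copy()


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------


class _Species:
    """Working state of one species across the cohort.

    Only still-active individuals are materialized in ``status``/``tag``
    (rows, in original order, indexed into the cohort by ``idx``); dead and
    frozen individuals keep their last recorded counts in the ``*_full``
    vectors.
    """

    __slots__ = (
        "slot", "params", "topo", "idx", "status", "tag",
        "alive", "death_time", "death_cause",
        "f_full", "ns_full", "nc_full",
        "f_hist", "ns_hist", "nc_hist",
    )

    def __init__(self, slot, params, topo, cohort, master_seed, record):
        self.slot = slot
        self.params = params
        self.topo = topo
        n = params.n_nodes
        self.idx = np.arange(cohort)
        self.status = np.ones((cohort, n), dtype=bool)
        self.tag = np.zeros((cohort, n), dtype=np.uint8)
        _prenatal(self.status, self.tag, params.f0,
                  _stream(master_seed, slot, 0, _P_PRENATAL))
        self.alive = np.ones(cohort, dtype=bool)
        self.death_time = np.full(cohort, -1, dtype=np.int64)
        self.death_cause = np.zeros(cohort, dtype=np.uint8)
        _propagate(topo, self.status, self.tag)  # prenatal damage may cascade
        self.f_full = self.status.sum(axis=1).astype(np.int16)
        self.ns_full = (self.tag == CAUSE_INTRINSIC).sum(axis=1).astype(np.int16)
        self.nc_full = (self.tag == CAUSE_COAGEING).sum(axis=1).astype(np.int16)
        self.f_hist: list | None = [] if record else None
        self.ns_hist: list | None = [] if record else None
        self.nc_hist: list | None = [] if record else None

    def sync_counts(self) -> None:
        self.f_full[self.idx] = self.status.sum(axis=1).astype(np.int16)
        self.ns_full[self.idx] = (self.tag == CAUSE_INTRINSIC).sum(axis=1).astype(np.int16)
        self.nc_full[self.idx] = (self.tag == CAUSE_COAGEING).sum(axis=1).astype(np.int16)

    def record(self) -> None:
        if self.f_hist is not None:
            self.f_hist.append(self.f_full.copy())
            self.ns_hist.append(self.ns_full.copy())
            self.nc_hist.append(self.nc_full.copy())

    def check_deaths(self, t: int) -> None:
        """Detect threshold crossings among materialized live rows; freeze them."""
        threshold = self.params.phi_T * self.params.n_nodes
        fcount = self.status.sum(axis=1)
        newly = self.alive[self.idx] & (fcount < threshold)
        if newly.any():
            ns = (self.tag == CAUSE_INTRINSIC).sum(axis=1)
            nc = (self.tag == CAUSE_COAGEING).sum(axis=1)
            cause = np.where(nc > ns, CAUSE_COAGEING, CAUSE_INTRINSIC).astype(np.uint8)
            who = self.idx[newly]
            self.death_time[who] = t
            self.death_cause[who] = cause[newly]
            self.alive[who] = False

    def compact(self) -> None:
        """Drop rows whose individual is no longer alive (dead or frozen).

        With per-individual topologies the block-diagonal dependee matrix is
        expensive to rebuild, so compaction is amortized: rows are dropped
        only once at least a quarter of the materialized rows are gone (dead
        rows are masked out of every update in the meantime).  Shared
        topologies compact eagerly — row slicing is cheap there.
        """
        keep = self.alive[self.idx]
        if keep.all():
            return
        if not self.topo.shared and keep.mean() > 0.75:
            return
        self.sync_counts()
        self.idx = self.idx[keep]
        self.status = self.status[keep]
        self.tag = self.tag[keep]
        self.topo.subset(keep)

    def freeze(self, frozen_ids: np.ndarray) -> None:
        self.alive[frozen_ids] = False
        self.compact()

    @property
    def n_active(self) -> int:
        return int(self.alive[self.idx].sum())

    def coageing_contribution(self) -> np.ndarray:
        """Functional fraction per cohort member; zero once dead/frozen.

        Rows that died earlier in the current step (detected but not yet
        compacted) are masked out too: a dead antagonist inflicts no damage
        from the moment its death is registered.
        """
        frac = np.zeros(len(self.alive))
        frac[self.idx] = self.status.sum(axis=1) / self.params.n_nodes
        frac[~self.alive] = 0.0
        return frac


def _round(species: _Species, probs, gen_mark, gen_repair, cause: int) -> None:
    """One damage round: direct marking, propagation, repair (in place).

    ``probs`` is a scalar or per-row vector of marking probabilities; the
    keyed generators are consulted only when the corresponding probability
    mass is non-zero, which keeps zero-rate regimes (e.g. the chess regime's
    d = 0) from spending random numbers they cannot use.
    """
    p = species.params
    act = species.alive[species.idx][:, None]
    scalar = np.isscalar(probs)
    any_mark = (probs > 0) if scalar else bool(np.any(probs > 0))
    if any_mark:
        u = gen_mark().random(species.status.shape)
        pcol = probs if scalar else np.asarray(probs)[:, None]
        new = species.status & (u < pcol) & act
        if new.any():
            species.tag[new] = cause
            species.status[new] = False
            # dead-but-materialized rows sit at a propagation fixed point,
            # so leaving them in the sweep changes nothing
            _propagate(species.topo, species.status, species.tag)
    if p.r > 0:
        u = gen_repair().random(species.status.shape)
        rep = (~species.status) & (u < p.r) & act
        if rep.any():
            species.status[rep] = True
            species.tag[rep] = CAUSE_NONE


def _coageing_rate(me: _Species, opp: Optional[_Species]) -> np.ndarray | float:
    """alpha = C * f_opp / N_opp per materialized row; dead antagonists
    contribute zero."""
    C = me.params.C
    if opp is None or C == 0.0:
        return 0.0
    alpha = C * opp.coageing_contribution()[me.idx]
    if np.any(alpha > 1.0):
        logger.warning(
            "co-ageing rate C*f/N exceeded 1 for %d individuals; clipped to 1",
            int(np.sum(alpha > 1.0)),
        )
        alpha = np.minimum(alpha, 1.0)
    return alpha


def _quiescent(spc: _Species, opp: Optional[_Species]) -> bool:
    """True when no surviving member of this species can ever change again."""
    if spc.n_active == 0:
        return True
    if spc.params.d > 0:
        return False
    if spc.params.C > 0 and opp is not None and opp.n_active > 0:
        if np.any(opp.status[opp.alive[opp.idx]]):
            return False
    # nothing can mark a node; pending repair still changes state (helps only)
    return not (spc.params.r > 0 and bool(np.any(~spc.status[spc.alive[spc.idx]])))


def _run_cohort(
    species_list: list[_Species],
    max_steps: int,
    winner_continues: bool,
    master_seed: int,
) -> CohortResult:
    cohort = len(species_list[0].alive)
    paired = len(species_list) == 2

    for spc in species_list:
        spc.check_deaths(0)
    if not winner_continues and paired:
        over = (species_list[0].death_time >= 0) | (species_list[1].death_time >= 0)
        for spc in species_list:
            spc.freeze(np.flatnonzero(over))
    for spc in species_list:
        spc.compact()
        spc.record()

    n_steps = 0
    for t in range(1, max_steps + 1):
        if all(spc.n_active == 0 for spc in species_list):
            break
        # no surviving network can receive damage -> state constant forever
        if all(_quiescent(spc, species_list[1 - i] if paired else None)
               for i, spc in enumerate(species_list)):
            break

        for i, spc in enumerate(species_list):
            opp = species_list[1 - i] if paired else None
            if spc.n_active == 0:
                continue
            slot = spc.slot
            _round(
                spc, spc.params.d,
                lambda: _stream(master_seed, slot, t, _P_MARK1),
                lambda: _stream(master_seed, slot, t, _P_REPAIR1),
                CAUSE_INTRINSIC,
            )
            _round(
                spc, _coageing_rate(spc, opp),
                lambda: _stream(master_seed, slot, t, _P_MARK2),
                lambda: _stream(master_seed, slot, t, _P_REPAIR2),
                CAUSE_COAGEING,
            )
            spc.check_deaths(t)
            spc.sync_counts()
        if not winner_continues and paired:
            # pair over at the end of the step in which either member died:
            # the survivor is frozen and censored (death_time stays -1)
            over = (species_list[0].death_time >= 0) | (species_list[1].death_time >= 0)
            for spc in species_list:
                spc.freeze(np.flatnonzero(over))
        for spc in species_list:
            spc.compact()
            spc.record()
        n_steps = t

    death_times = np.stack([spc.death_time for spc in species_list])
    death_causes = np.stack([spc.death_cause for spc in species_list])
    rec = species_list[0].f_hist is not None
    return CohortResult(
        cohort_size=cohort,
        n_species=len(species_list),
        params=tuple(spc.params for spc in species_list),
        death_times=death_times,
        death_causes=death_causes,
        n_steps=n_steps,
        f=np.stack([np.stack(s.f_hist) for s in species_list]) if rec else None,
        ns=np.stack([np.stack(s.ns_hist) for s in species_list]) if rec else None,
        nc=np.stack([np.stack(s.nc_hist) for s in species_list]) if rec else None,
    )


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def simulate_cohort(
    topologies_a: Sequence[DependencyNetwork] | DependencyNetwork,
    topologies_b: Sequence[DependencyNetwork] | DependencyNetwork,
    params_a: SpeciesParams,
    params_b: SpeciesParams,
    cohort_size: int,
    max_steps: int = 5000,
    winner_continues: bool = True,
    master_seed: int = 0,
    record_trajectories: bool = True,
) -> CohortResult:
    """Simulate a cohort of co-ageing network pairs.

    Every pair consists of one species-A and one species-B network ageing
    against each other.  Pass a single :class:`DependencyNetwork` (or a
    length-1 list) for a shared topology, or one network per individual for
    randomized structures.  Individuals still alive at ``max_steps`` are
    censored, never counted as deaths.

    The run is reproducible from ``master_seed`` alone (given the
    topologies); randomness is keyed per species slot, step and purpose, so
    no result depends on any iteration order.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    nets_a = [topologies_a] if isinstance(topologies_a, DependencyNetwork) else list(topologies_a)
    nets_b = [topologies_b] if isinstance(topologies_b, DependencyNetwork) else list(topologies_b)
    topo_a = _CohortTopology(nets_a, cohort_size)
    topo_b = _CohortTopology(nets_b, cohort_size)
    if topo_a.n_nodes != params_a.n_nodes or topo_b.n_nodes != params_b.n_nodes:
        raise ValueError("topology size disagrees with SpeciesParams.n_nodes")
    species = [
        _Species(0, params_a, topo_a, cohort_size, master_seed, record_trajectories),
        _Species(1, params_b, topo_b, cohort_size, master_seed, record_trajectories),
    ]
    return _run_cohort(species, max_steps, winner_continues, master_seed)


def simulate_solo_cohort(
    topologies: Sequence[DependencyNetwork] | DependencyNetwork,
    params: SpeciesParams,
    cohort_size: int,
    max_steps: int = 5000,
    master_seed: int = 0,
    species_slot: int = 0,
    record_trajectories: bool = True,
) -> CohortResult:
    """Age one species with no antagonist (the solo / typical-ageing model).

    With ``species_slot`` matching the slot the species occupies in a paired
    run (0 for A, 1 for B), the random draws are identical to that paired
    run's, so a paired run with ``C = 0`` reproduces the solo trajectories
    exactly.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    nets = [topologies] if isinstance(topologies, DependencyNetwork) else list(topologies)
    topo = _CohortTopology(nets, cohort_size)
    if topo.n_nodes != params.n_nodes:
        raise ValueError("topology size disagrees with SpeciesParams.n_nodes")
    species = [_Species(species_slot, params, topo, cohort_size, master_seed, record_trajectories)]
    return _run_cohort(species, max_steps, True, master_seed)


def simulate_pair(
    net_a: DependencyNetwork,
    net_b: DependencyNetwork,
    params_a: SpeciesParams,
    params_b: SpeciesParams,
    max_steps: int = 5000,
    winner_continues: bool = True,
    master_seed: int = 0,
) -> PairTrajectory:
    """Simulate a single A/B pair and return its full trajectory."""
    result = simulate_cohort(
        net_a, net_b, params_a, params_b,
        cohort_size=1, max_steps=max_steps,
        winner_continues=winner_continues, master_seed=master_seed,
    )
    return result[0]
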