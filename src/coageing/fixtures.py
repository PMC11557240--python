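"""Deterministic synthetic fixtures: PGN archives, hazard targets, toy networks.

Everything any pipeline stage needs can be generated here, so the whole
package is exercisable with no external download.  The PGN archives are
*synthetic*: tag pairs are fully realistic, but the movetext is filler SAN
whose only meaningful property is its ply count — never feed it to a chess
engine.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np

from .chess import GlickoPlayer, expected_outcome, rating_gap_for_expected
from .config import RunConfig, run_cohort
from .demography import demography_from_result, write_hazard_table
from .network import DependencyNetwork

__all__ = [
    "make_pgn_archive",
    "make_hazard_target",
    "chain_network",
    "two_dependee_motif",
]

# filler SAN cycle for synthetic movetext (plausible-looking, not legal play)
_SAN_CYCLE = [
    "e4", "e5", "Nf3", "Nc6", "Bb5", "a6", "Ba4", "Nf6", "O-O", "Be7",
    "Re1", "b5", "Bb3", "d6", "c3", "O-O", "h3", "Na5", "Bc2", "c5",
    "d4", "Qc7", "Nbd2", "Nc6", "d5", "Nd8", "a4", "Rb8", "axb5", "axb5",
]


def _movetext(ply: int, result_token: str) -> str:
    tokens = []
    for i in range(ply):
        if i % 2 == 0:
            tokens.append(f"{i // 2 + 1}.")
        tokens.append(_SAN_CYCLE[i % len(_SAN_CYCLE)])
    tokens.append(result_token)
    # wrap lines near 80 columns as PGN exporters do
    lines, line = [], ""
    for tok in tokens:
        if line and len(line) + 1 + len(tok) > 79:
            lines.append(line)
            line = tok
        else:
            line = f"{line} {tok}".strip()
    lines.append(line)
    return "\n".join(lines)


def make_pgn_archive(
    path,
    n_decided: int = 400,
    expected_white: float = 0.75,
    rd: float = 50.0,
    base_rating: float = 1800.0,
    time_control: int = 300,
    mean_turns: float = 35.0,
    n_draws: int = 0,
    n_forfeits: int = 0,
    n_missing_elo: int = 0,
    n_other_time_control: int = 0,
    seed: int = 0,
    write_sidecar: bool = True,
) -> dict:
    """Write a synthetic PGN archive with controlled composition.

    The decided games pit a white rated ``base_rating + gap`` against a black
    at ``base_rating``, where the gap is chosen so the Glicko expected
    outcome for white equals ``expected_white`` exactly (given equal RDs);
    white then actually wins each decided game with that same probability,
    so the archive's empirical white-win fraction estimates its expected
    outcome.  Draw/forfeit/missing-tag/off-time-control games are appended
    in controlled numbers to exercise the filters.  Game lengths are Poisson
    around ``mean_turns`` full moves (min 2).  Deterministic given ``seed``;
    returns the composition dict (also written to ``<path>.json`` unless
    disabled).
    """
    rng = np.random.default_rng(seed)
    gap = rating_gap_for_expected(expected_white, rd, rd)
    white = GlickoPlayer(base_rating + gap, rd)
    black = GlickoPlayer(base_rating, rd)
    games = []

    def lengths(n: int) -> np.ndarray:
        return np.maximum(rng.poisson(mean_turns, size=n), 2)

    for turns in lengths(n_decided):
        white_wins = rng.random() < expected_white
        games.append(
            dict(result="1-0" if white_wins else "0-1", turns=int(turns),
                 termination="Checkmate", tc=time_control, tagged=True)
        )
    for turns in lengths(n_draws):
        games.append(dict(result="1/2-1/2", turns=int(turns),
                          termination="Normal", tc=time_control, tagged=True))
    for turns in lengths(n_forfeits):
        games.append(dict(result="1-0", turns=int(turns),
                          termination="Forfeit", tc=time_control, tagged=True))
    for turns in lengths(n_missing_elo):
        games.append(dict(result="1-0", turns=int(turns),
                          termination="Checkmate", tc=time_control, tagged=False))
    for turns in lengths(n_other_time_control):
        games.append(dict(result="1-0", turns=int(turns),
                          termination="Checkmate", tc=time_control * 2, tagged=True))
    order = rng.permutation(len(games))

    with open(path, "w") as fh:
        for rank, idx in enumerate(order):
            game = games[idx]
            fh.write(f'[Event "synthetic fixture"]\n')
            fh.write(f'[Site "coageing.fixtures"]\n')
            fh.write(f'[Round "{rank + 1}"]\n')
            fh.write(f'[White "White{rank}"]\n[Black "Black{rank}"]\n')
            if game["tagged"]:
                fh.write(f'[WhiteElo "{white.rating:.0f}"]\n')
                fh.write(f'[BlackElo "{black.rating:.0f}"]\n')
                fh.write(f'[WhiteRD "{white.rd:.1f}"]\n[BlackRD "{black.rd:.1f}"]\n')
            fh.write(f'[TimeControl "{game["tc"]}+0"]\n')
            fh.write(f'[Termination "{game["termination"]}"]\n')
            fh.write(f'[Result "{game["result"]}"]\n\n')
            ply = 2 * game["turns"]
            fh.write(_movetext(ply, game["result"]) + "\n\n")

    composition = {
        "n_games": len(games),
        "n_decided": n_decided,
        "n_draws": n_draws,
        "n_forfeits": n_forfeits,
        "n_missing_elo": n_missing_elo,
        "n_other_time_control": n_other_time_control,
        "expected_white": expected_white,
        "achieved_expected_white": expected_outcome(white, black),
        "white_rating": white.rating,
        "black_rating": black.rating,
        "rd": rd,
        "time_control": time_control,
        "seed": seed,
    }
    if write_sidecar:
        with open(str(path) + ".json", "w") as fh:
            json.dump(composition, fh, indent=2)
    return composition


def make_hazard_target(
    path,
    config: RunConfig,
    species: int = 0,
    write_sidecar: bool = True,
) -> dict:
    """Simulate a cohort and write its hazard table as a calibration target.

    The sidecar ``<path>.json`` records the true generating parameters, so
    parameter-recovery exercises know the ground truth.
    """
    result = run_cohort(config, record_trajectories=False)
    table = demography_from_result(result, species=species)
    write_hazard_table(table, path)
    species_params = config.species_a if species == 0 else config.species_b
    truth = {
        "species": species,
        "true_params": {
            "n_nodes": species_params.n_nodes,
            "d": species_params.d,
            "r": species_params.r,
            "C": species_params.C,
            "f0": species_params.f0,
            "phi_T": species_params.phi_T,
        },
        "cohort_size": config.cohort_size,
        "master_seed": config.master_seed,
        "mean_lifespan": result.mean_lifespan(species),
    }
    if write_sidecar:
        with open(str(path) + ".json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return truth


def chain_network() -> DependencyNetwork:
    """Hand-checkable 3-node chain: 1 depends on 0, 2 depends on 1.

    Killing node 0 cascades: node 1 fails in the first propagation sweep
    (1/1 dependees down), node 2 in the second.
    """
    return DependencyNetwork(
        3, dependees=[[], [0], [1]], dependents=[[1], [2], []], seed_size=3
    )


def two_dependee_motif() -> DependencyNetwork:
    """Node 2 depends on nodes 0 and 1: fails only when both are down.

    One dysfunctional dependee is exactly half — not *more* than half — so
    node 2 survives it.
    """
    return DependencyNetwork(
        3, dependees=[[], [], [0, 1]], dependents=[[2], [2], []], seed_size=3
    )
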