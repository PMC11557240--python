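"""Chess games as co-ageing cohorts: archive -> filters -> hazard curves.

Builds a synthetic PGN archive with a known composition, filters it the way
survival analysis of real server games is set up (a narrow Glicko
expected-outcome band, one time control, no draws or forfeits), and turns
the games into per-colour survival tables under the winner-continues-to-live
convention.  Then simulates the matching network regime: two equal-sized
defence networks with no intrinsic damage, no prenatal damage and no repair,
coupled only through their co-ageing constants.
"""

import tempfile
from pathlib import Path

import numpy as np

from coageing import (
    chess_regime_params,
    demography_from_result,
    expected_outcome,
    filter_games,
    games_to_demography,
    grow_network,
    read_pgn_archive,
    simulate_cohort,
)
from coageing.fixtures import make_pgn_archive

SEED = 5

with tempfile.TemporaryDirectory() as tmp:
    pgn = Path(tmp) / "archive.pgn"
    comp = make_pgn_archive(
        pgn, n_decided=400, n_draws=25, n_forfeits=15, n_missing_elo=5,
        expected_white=0.75, seed=SEED,
    )
    games = read_pgn_archive(pgn)
    kept = filter_games(games, 0.7, 0.8, time_control=300)

print(f"archive: {comp['n_games']} games, {games.n_skipped} skipped (missing Elo)")
print(f"kept in expected-outcome band [0.70, 0.80]: {len(kept)} "
      f"(draws/forfeits excluded)")
e = expected_outcome(kept[0].white, kept[0].black)
frac = np.mean([g.result == "white_win" for g in kept])
print(f"Glicko expected outcome for white: {e:.3f}; realized win fraction {frac:.3f}")

tables = games_to_demography(kept)
for colour in ("white", "black"):
    df = tables[colour]
    deaths = int((df["d_s"] + df["d_c"]).sum())
    print(f"{colour:>6}: {deaths} losses, risk set settles at S = {int(df['S'].iloc[-1])} "
          f"(winners censored alive)")

# matching simulation regime: damage flows only between the two networks
white_p, black_p = chess_regime_params(n_nodes=40, c_white=0.05, c_black=0.08)
res = simulate_cohort(
    grow_network(40, SEED), grow_network(40, SEED + 1),
    white_p, black_p, 2000, max_steps=2000, master_seed=SEED,
    record_trajectories=False,
)
dead_w = res.death_times[0] >= 0
dead_b = res.death_times[1] >= 0
print(f"\nsimulated chess regime (C_white=0.05 < C_black=0.08, phi_T=0.15):")
print(f"  exactly one death per pair: {(dead_w ^ dead_b).all()}")
print(f"  white loses {dead_w.mean():.1%} of games (receives less damage per turn)")
mu_w = demography_from_result(res, 0)["mu"]
print(f"  white hazard after last game ends: {float(mu_w.iloc[-1]):.3f} "
      "(winners never die)")
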