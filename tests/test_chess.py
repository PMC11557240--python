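"""Glicko expected outcomes, PGN parsing, filtering, per-colour demography."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coageing import (
    GameRecord,
    GlickoPlayer,
    chess_regime_params,
    expected_outcome,
    filter_games,
    games_to_demography,
    glicko_g,
    rating_gap_for_expected,
    read_pgn_archive,
)
from coageing.chess import Q
from coageing.fixtures import make_pgn_archive


class TestGlicko:
    def test_zero_uncertainty_full_weight(self):
        assert glicko_g(0.0) == 1.0

    def test_half_attenuation_closed_form(self):
        # 3 q^2 x / pi^2 = 3  =>  g = 1/sqrt(4) = 1/2
        x = math.pi**2 / Q**2
        assert glicko_g(x) == pytest.approx(0.5)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            glicko_g(-1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1e6), st.floats(1, 1e6))
    def test_strictly_decreasing(self, x, dx):
        assert glicko_g(x + dx) < glicko_g(x) <= 1.0

    def test_equal_ratings_give_half(self):
        a, b = GlickoPlayer(1500, 30), GlickoPlayer(1500, 250)
        assert expected_outcome(a, b) == pytest.approx(0.5)

    def test_classic_elo_limit_400_points(self):
        a, b = GlickoPlayer(1900, 0), GlickoPlayer(1500, 0)
        assert expected_outcome(a, b) == pytest.approx(10 / 11)

    @settings(max_examples=50, deadline=None)
    @given(
        ri=st.floats(500, 2900),
        rj=st.floats(500, 2900),
        rdi=st.floats(0, 350),
        rdj=st.floats(0, 350),
    )
    def test_complement_identity(self, ri, rj, rdi, rdj):
        a, b = GlickoPlayer(ri, rdi), GlickoPlayer(rj, rdj)
        assert expected_outcome(a, b) + expected_outcome(b, a) == pytest.approx(1.0)

    def test_increasing_in_rating_gap(self):
        base = GlickoPlayer(1500, 50)
        es = [expected_outcome(GlickoPlayer(1500 + gap, 50), base)
              for gap in (0, 100, 200, 400)]
        assert all(x < y for x, y in zip(es, es[1:]))

    def test_gap_inversion(self):
        gap = rating_gap_for_expected(0.75, 50, 50)
        e = expected_outcome(GlickoPlayer(1500 + gap, 50), GlickoPlayer(1500, 50))
        assert e == pytest.approx(0.75)


@pytest.fixture(scope="module")
def archive(tmp_path_factory):
    path = tmp_path_factory.mktemp("pgn") / "fixture.pgn"
    comp = make_pgn_archive(
        path,
        n_decided=40,
        n_draws=5,
        n_forfeits=3,
        n_missing_elo=2,
        n_other_time_control=4,
        expected_white=0.75,
        seed=11,
    )
    return path, comp


class TestPGNReading:
    def test_reads_all_tagged_games(self, archive):
        path, comp = archive
        games = read_pgn_archive(path)
        assert len(games) == comp["n_games"] - comp["n_missing_elo"]
        assert games.n_skipped == comp["n_missing_elo"]

    def test_lengths_are_full_moves(self, tmp_path):
        path = tmp_path / "odd.pgn"
        path.write_text(
            '[White "a"]\n[Black "b"]\n[WhiteElo "1600"]\n[BlackElo "1500"]\n'
            '[Result "1-0"]\n\n'
            + " ".join(f"{i + 1}. x y" for i in range(17))
            + " 18. z 1-0\n"
        )
        games = read_pgn_archive(path)
        assert games[0].length_turns == 18  # 35 ply -> ceil(35/2)

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            read_pgn_archive(tmp_path / "missing.pgn")

    def test_no_parsable_games(self, tmp_path):
        path = tmp_path / "bad.pgn"
        path.write_text('[White "a"]\n[Black "b"]\n\n1. e4 e5 *\n')
        with pytest.raises(ValueError):
            read_pgn_archive(path)

    def test_comments_and_variations_not_counted(self, tmp_path):
        path = tmp_path / "annot.pgn"
        path.write_text(
            '[White "a"]\n[Black "b"]\n[WhiteElo "1600"]\n[BlackElo "1500"]\n'
            '[Result "0-1"]\n\n'
            "1. e4 {best by test} e5 (1... c5 2. Nf3) 2. Nf3 $1 Nc6 0-1\n"
        )
        games = read_pgn_archive(path)
        assert games[0].length_turns == 2  # 4 real ply


class TestFiltering:
    def test_band_and_exclusions(self, archive):
        path, comp = archive
        games = read_pgn_archive(path)
        kept = filter_games(games, 0.7, 0.8, time_control=300)
        # decided games sit at E=0.75 exactly; draws/forfeits/other-TC drop out
        assert len(kept) == comp["n_decided"]
        assert all(g.result != "draw" for g in kept)

    def test_off_band_empties(self, archive):
        path, _ = archive
        games = read_pgn_archive(path)
        assert len(filter_games(games, 0.55, 0.65, time_control=300)) == 0

    def test_idempotent_and_order_preserving(self, archive):
        path, _ = archive
        games = read_pgn_archive(path)
        once = filter_games(games, 0.7, 0.8, time_control=300)
        twice = filter_games(once, 0.7, 0.8, time_control=300)
        assert list(once) == list(twice)

    def test_bad_band(self, archive):
        path, _ = archive
        games = read_pgn_archive(path)
        with pytest.raises(ValueError):
            filter_games(games, 0.8, 0.7)


class TestGamesToDemography:
    def test_forced_example(self):
        games = [
            GameRecord(GlickoPlayer(1700), GlickoPlayer(1500), "white_win",
                       "checkmate", 300, 30)
            for _ in range(10)
        ]
        tables = games_to_demography(games)
        black = tables["black"]
        assert black["mu"].iloc[30] == 1.0
        white = tables["white"]
        assert (white["mu"].fillna(0) == 0).all()  # winners never die
        assert (white["S"] == 10).all()

    def test_accounting_closes(self, archive):
        path, _ = archive
        games = filter_games(read_pgn_archive(path), 0.7, 0.8, time_control=300)
        tables = games_to_demography(games)
        for colour in ("white", "black"):
            df = tables[colour]
            deaths = df["d_s"] + df["d_c"]
            # survivors at t plus deaths before t equal the full game count
            assert ((df["S"] + deaths.cumsum() - deaths) == len(games)).all()

    def test_win_fraction_matches_construction(self, archive):
        path, comp = archive
        games = filter_games(read_pgn_archive(path), 0.7, 0.8, time_control=300)
        frac_white = np.mean([g.result == "white_win" for g in games])
        se = math.sqrt(0.75 * 0.25 / len(games))
        assert abs(frac_white - comp["expected_white"]) < 3 * se

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            games_to_demography([])


class TestChessRegime:
    def test_constraints(self):
        white, black = chess_regime_params(40, 0.05, 0.08)
        for p in (white, black):
            assert p.d == 0 and p.r == 0 and p.f0 == 1.0
            assert p.phi_T == 0.15
            assert p.n_nodes == 40
        assert white.C == 0.05 and black.C == 0.08
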