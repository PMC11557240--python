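"""Survival counts, hazards, interval mortality, smoothing, bump detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coageing import (
    SpeciesParams,
    cause_specific_hazards,
    demography_from_result,
    detect_bump,
    hazard_curve,
    interval_mortality,
    read_hazard_table,
    restricted_mean_lifespan,
    simulate_solo_cohort,
    smooth_hazard,
    write_hazard_table,
)
from coageing.engine import CAUSE_COAGEING, CAUSE_INTRINSIC
from coageing.network import single_node_network


class TestHazardCurve:
    def test_ten_percent_per_step(self):
        # S = [100, 90, 81] corresponds to 10 deaths at t=0 and 9 at t=1
        dt = np.array([0] * 10 + [1] * 9 + [2] * 81)
        df = hazard_curve(dt, max_t=1)
        assert list(df["S"]) == [100, 90]
        assert np.allclose(df["mu"], [0.10, 0.10])

    def test_certain_death_gives_unit_hazard(self):
        df = hazard_curve(np.full(50, 1), max_t=1)
        assert df["mu"].iloc[1] == 1.0
        assert df["S"].iloc[1] == 50

    def test_s_zero_is_nan_not_zero(self):
        dt = np.array([0, 0, 1])
        df = hazard_curve(dt, max_t=3)
        assert df["S"].iloc[2] == 0
        assert np.isnan(df["mu"].iloc[2]) and np.isnan(df["mu"].iloc[3])

    def test_censored_stay_in_risk_set(self):
        dt = np.array([1, 1, -1, -1])
        df = hazard_curve(dt, max_t=3)
        assert list(df["S"]) == [4, 4, 2, 2]
        assert df["mu"].iloc[3] == 0.0

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            hazard_curve(np.array([], dtype=int))

    def test_geometric_cohort_flat_hazard(self):
        net = single_node_network()
        p = SpeciesParams(n_nodes=1, d=0.1, r=0.0, C=0.0, phi_T=0.5)
        res = simulate_solo_cohort(net, p, 10_000, max_steps=300, master_seed=17)
        df = hazard_curve(res.death_times[0])
        big = df[df["S"] >= 100]
        se = np.sqrt(0.1 * 0.9 / big["S"].to_numpy())
        dev = np.abs(big["mu"].to_numpy()[1:] - 0.1)  # no deaths possible at t=0
        assert (dev <= 3 * se[1:]).all()


class TestCauseSpecific:
    def test_arithmetic_from_definition(self):
        dt = np.array([0] * 10 + [0] * 30 + [1] * 160)
        causes = np.array([CAUSE_INTRINSIC] * 10 + [CAUSE_COAGEING] * 30
                          + [CAUSE_INTRINSIC] * 160)
        df = cause_specific_hazards(dt, causes, max_t=0)
        assert df["S"].iloc[0] == 200
        assert df["mu_s"].iloc[0] == pytest.approx(0.05)
        assert df["mu_c"].iloc[0] == pytest.approx(0.15)
        assert df["mu"].iloc[0] == pytest.approx(0.20)

    def test_single_cause_collapses(self):
        dt = np.array([1, 2, 2, 3])
        causes = np.full(4, CAUSE_INTRINSIC)
        df = cause_specific_hazards(dt, causes)
        assert (df["mu_c"].fillna(0) == 0).all()
        assert np.allclose(df["mu_s"], df["mu"], equal_nan=True)

    def test_additivity_exact_on_simulated_cohort(self, net100, net100_b, frail_pair):
        from coageing import simulate_cohort

        pa, pb = frail_pair
        res = simulate_cohort(net100, net100_b, pa, pb, 500, max_steps=3000,
                              master_seed=2, record_trajectories=False)
        for s in range(2):
            df = demography_from_result(res, species=s)
            ok = df["S"] > 0
            assert np.array_equal(
                (df["mu_s"] + df["mu_c"])[ok].to_numpy(), df["mu"][ok].to_numpy()
            )

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValueError):
            cause_specific_hazards(np.array([1]), np.array([7]))

    def test_death_without_cause_rejected(self):
        with pytest.raises(ValueError):
            cause_specific_hazards(np.array([1]), np.array([0]))


class TestIntervalMortality:
    def test_no_deaths_is_zero(self):
        assert interval_mortality(100, 100, 5) == 0.0

    def test_delta_one_reduces_to_hazard(self):
        # identical to [S(t) - S(t+1)] / S(t) on the same counts
        assert interval_mortality(100, 90, 1) == pytest.approx(0.10)
        df = hazard_curve(np.array([0] * 10 + [-1] * 90), max_t=0)
        assert interval_mortality(100, 90, 1) == pytest.approx(df["mu"].iloc[0])

    def test_annualization(self):
        assert interval_mortality(100, 81, 2) == pytest.approx(0.10)

    def test_increasing_survivors_rejected(self):
        with pytest.raises(ValueError):
            interval_mortality(90, 100, 1)

    @settings(max_examples=50, deadline=None)
    @given(
        s_i=st.integers(1, 10_000),
        drop=st.integers(0, 9_000),
        dt=st.integers(1, 50),
    )
    def test_bounds(self, s_i, drop, dt):
        s_f = max(1, s_i - drop)
        m = interval_mortality(s_i, s_f, dt)
        assert 0.0 <= m < 1.0


class TestSmoothing:
    def test_window_one_is_identity(self):
        x = np.array([0.1, 0.4, 0.2])
        assert np.array_equal(smooth_hazard(x, 1), x)

    def test_constant_series_unchanged(self):
        x = np.full(11, 0.3)
        assert np.allclose(smooth_hazard(x, 5), x)

    def test_hand_average(self):
        out = smooth_hazard(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), 3)
        assert out[1] == pytest.approx(1 / 3)
        assert out[2] == pytest.approx(2 / 3)
        assert out[3] == pytest.approx(1 / 3)
        assert out[0] == pytest.approx(0.5)  # truncated end window

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_hazard(np.ones(5), 4)


class TestBumpDetection:
    def test_monotone_has_no_bump(self):
        rep = detect_bump(np.linspace(0, 1, 50))
        assert rep.maxima == [] and rep.minima == [] and not rep.has_bump

    def test_constant_has_no_extrema(self):
        rep = detect_bump(np.full(20, 0.2))
        assert not rep.has_bump

    def test_rise_dip_rise_is_one_bump(self):
        x = np.concatenate([np.linspace(0, 0.5, 20), np.linspace(0.5, 0.2, 10),
                            np.linspace(0.2, 1.0, 20)])
        rep = detect_bump(x)
        assert len(rep.bumps) == 1
        mx, mn = rep.bumps[0]
        assert 17 <= mx <= 21 and 27 <= mn <= 31

    def test_min_drop_filters_shallow_wiggles(self):
        x = np.concatenate([np.linspace(0, 0.5, 20), [0.499], np.linspace(0.5, 1.0, 20)])
        assert detect_bump(x).has_bump
        assert not detect_bump(x, min_drop=0.01).has_bump


class TestRestrictedMean:
    def test_all_dead_matches_clipped_mean(self):
        dt = np.array([2, 4, 6])
        assert restricted_mean_lifespan(dt, 100) == pytest.approx(4.0)
        assert restricted_mean_lifespan(dt, 5) == pytest.approx((2 + 4 + 5) / 3)

    def test_censored_count_as_horizon(self):
        assert restricted_mean_lifespan(np.array([2, -1]), 10) == pytest.approx(6.0)


def test_hazard_table_roundtrip(tmp_path):
    dt = np.array([1, 2, 2, -1])
    causes = np.array([CAUSE_INTRINSIC, CAUSE_COAGEING, CAUSE_INTRINSIC, 0])
    df = cause_specific_hazards(dt, causes)
    path = tmp_path / "hazard.tsv"
    write_hazard_table(df, path)
    back = read_hazard_table(path)
    assert list(back.columns) == list(df.columns)
    assert np.allclose(back["mu"], df["mu"], equal_nan=True)
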