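"""Unit and property tests for the two-round co-ageing dynamics."""

import logging

import numpy as np
import pytest

from coageing import (
    SpeciesParams,
    apply_prenatal_damage,
    grow_network,
    label_network_death,
    propagate_damage,
    simulate_cohort,
    simulate_pair,
    simulate_solo_cohort,
)
from coageing.engine import CAUSE_COAGEING, CAUSE_INTRINSIC, CAUSE_NONE
from coageing.network import single_node_network


class TestSpeciesParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"d": 1.2},
            {"d": -0.1},
            {"r": 2.0},
            {"C": -0.01},
            {"f0": 0.0},
            {"f0": 1.5},
            {"phi_T": 0.0},
            {"f0": 0.05, "phi_T": 0.10},  # threshold above initial function
        ],
    )
    def test_rejects_out_of_range(self, kw):
        with pytest.raises(ValueError):
            SpeciesParams(n_nodes=10, **kw)


class TestPrenatalDamage:
    def test_f0_one_leaves_everything_functional(self, net100):
        status, tag = apply_prenatal_damage(net100, 1.0, np.random.default_rng(0))
        assert status.all() and (tag == CAUSE_NONE).all()

    def test_exact_count_and_intrinsic_tag(self, net100):
        status, tag = apply_prenatal_damage(net100, 0.9, np.random.default_rng(0))
        assert (~status).sum() == 10
        assert (tag[~status] == CAUSE_INTRINSIC).all()
        assert (tag[status] == CAUSE_NONE).all()

    def test_deterministic_given_rng(self, net100):
        s1, _ = apply_prenatal_damage(net100, 0.8, np.random.default_rng(42))
        s2, _ = apply_prenatal_damage(net100, 0.8, np.random.default_rng(42))
        assert np.array_equal(s1, s2)

    def test_rejects_bad_fraction(self, net100):
        with pytest.raises(ValueError):
            apply_prenatal_damage(net100, 0.0, np.random.default_rng(0))


class TestPropagation:
    def test_both_dependees_down_kills_node(self, motif):
        status = np.array([False, False, True])
        tag = np.array([CAUSE_INTRINSIC, CAUSE_INTRINSIC, CAUSE_NONE], dtype=np.uint8)
        s, t = propagate_damage(motif, status, tag)
        assert not s[2] and t[2] == CAUSE_INTRINSIC

    def test_exactly_half_is_not_more_than_half(self, motif):
        status = np.array([False, True, True])
        tag = np.array([CAUSE_INTRINSIC, CAUSE_NONE, CAUSE_NONE], dtype=np.uint8)
        s, _ = propagate_damage(motif, status, tag)
        assert s[2]  # one of two dependees down: survives

    def test_chain_cascades_to_fixed_point(self, chain):
        status = np.array([False, True, True])
        tag = np.array([CAUSE_COAGEING, CAUSE_NONE, CAUSE_NONE], dtype=np.uint8)
        s, t = propagate_damage(chain, status, tag)
        assert not s.any()  # a -> b -> c all fall
        assert (t == CAUSE_COAGEING).all()  # cause inherited down the chain

    def test_idempotent(self, net100):
        rng = np.random.default_rng(3)
        status = rng.random(100) > 0.3
        tag = np.where(status, CAUSE_NONE, CAUSE_INTRINSIC).astype(np.uint8)
        s1, t1 = propagate_damage(net100, status, tag)
        s2, t2 = propagate_damage(net100, s1, t1)
        assert np.array_equal(s1, s2) and np.array_equal(t1, t2)

    def test_majority_cause_inheritance_tie_goes_intrinsic(self, motif):
        status = np.array([False, False, True])
        tag = np.array([CAUSE_INTRINSIC, CAUSE_COAGEING, CAUSE_NONE], dtype=np.uint8)
        _, t = propagate_damage(motif, status, tag)
        assert t[2] == CAUSE_INTRINSIC  # 1-1 split resolves to intrinsic


class TestDeathLabel:
    @pytest.mark.parametrize(
        "ns, nc, expected",
        [(80, 15, "intrinsic"), (15, 80, "coageing"), (45, 45, "intrinsic")],
    )
    def test_majority_rule_with_tie_break(self, ns, nc, expected):
        assert label_network_death(ns, nc) == expected


class TestStepAndPair:
    def test_no_damage_sources_means_stasis(self, net100, net100_b):
        p = SpeciesParams(n_nodes=100, d=0.0, r=0.0, C=0.0, f0=1.0)
        traj = simulate_pair(net100, net100_b, p, p, max_steps=50, master_seed=1)
        assert traj.a.censored and traj.b.censored
        assert (traj.a.f == 100).all()

    def test_certain_damage_kills_in_one_step(self, net100, net100_b):
        pa = SpeciesParams(n_nodes=100, d=1.0, r=0.0, C=0.0)
        pb = SpeciesParams(n_nodes=100, d=0.0, r=0.0, C=0.0)
        traj = simulate_pair(net100, net100_b, pa, pb, max_steps=10, master_seed=1)
        assert traj.a.death_time == 1 and traj.a.death_cause == "intrinsic"
        assert traj.a.f[1] == 0

    def test_dead_antagonist_inflicts_nothing(self, net100, net100_b):
        # A (updated first) dies at t=1; B's only damage source is A, and a
        # dead antagonist contributes alpha = 0 already within the same step,
        # so B never takes any damage and is censored.
        pa = SpeciesParams(n_nodes=100, d=1.0, r=0.0, C=0.0)
        pb = SpeciesParams(n_nodes=100, d=0.0, r=0.0, C=0.5)
        traj = simulate_pair(net100, net100_b, pa, pb, max_steps=200, master_seed=2)
        assert traj.a.death_time == 1
        assert traj.b.censored
        assert (traj.b.f == 100).all()

    def test_repair_one_grants_immortality(self, net100, net100_b):
        pa = SpeciesParams(n_nodes=100, d=0.5, r=1.0, C=0.0)
        pb = SpeciesParams(n_nodes=100, d=0.5, r=1.0, C=0.015)
        res = simulate_cohort(net100, net100_b, pa, pb, 50, max_steps=300, master_seed=3)
        assert (res.death_times < 0).all()

    def test_alpha_clipping_warns(self, net100, net100_b, caplog):
        pa = SpeciesParams(n_nodes=100, d=0.0, r=0.0, C=1.5)  # alpha = 1.5 at f_B=1
        pb = SpeciesParams(n_nodes=100, d=0.0, r=0.0, C=0.0)
        with caplog.at_level(logging.WARNING, logger="coageing.engine"):
            traj = simulate_pair(net100, net100_b, pa, pb, max_steps=5, master_seed=1)
        assert any("clipped" in rec.message for rec in caplog.records)
        assert traj.a.death_time == 1  # certain co-ageing marking kills at once
        assert traj.a.death_cause == "coageing"


class TestConservation:
    def test_f_ns_nc_sum_to_n_every_step(self, net100, net100_b, frail_pair):
        pa, pb = frail_pair
        res = simulate_cohort(net100, net100_b, pa, pb, 200, max_steps=2000, master_seed=11)
        for s in range(2):
            total = res.f[s].astype(int) + res.ns[s].astype(int) + res.nc[s].astype(int)
            assert (total == 100).all()


class TestDecoupling:
    def test_uncoupled_pair_matches_solo_bitwise(self, net100, net100_b, frail_pair):
        _, pb = frail_pair
        pa0 = SpeciesParams(n_nodes=100, d=0.002, r=0.02, C=0.0)
        paired = simulate_cohort(net100, net100_b, pa0, pb, 300, max_steps=3000, master_seed=9)
        solo = simulate_solo_cohort(net100, pa0, 300, max_steps=3000, master_seed=9)
        assert np.array_equal(paired.death_times[0], solo.death_times[0])
        assert np.array_equal(paired.death_causes[0], solo.death_causes[0])
        T = min(paired.f.shape[1], solo.f.shape[1])
        assert np.array_equal(paired.f[0, :T], solo.f[0, :T])
        assert np.array_equal(paired.ns[0, :T], solo.ns[0, :T])

    def test_uncoupled_deaths_all_intrinsic(self, net100, net100_b, frail_pair):
        _, pb = frail_pair
        pa0 = SpeciesParams(n_nodes=100, d=0.004, r=0.0, C=0.0)
        res = simulate_cohort(net100, net100_b, pa0, pb, 200, max_steps=2000, master_seed=4)
        dead = res.death_times[0] >= 0
        assert dead.all()
        assert (res.death_causes[0][dead] == CAUSE_INTRINSIC).all()


class TestSingleNodeClosedForm:
    def test_geometric_lifespans(self):
        # one node, no repair, no propagation: death time ~ Geometric(d)
        net = single_node_network()
        p = SpeciesParams(n_nodes=1, d=0.5, r=0.0, C=0.0, phi_T=0.5)
        res = simulate_solo_cohort(net, p, 4000, max_steps=200, master_seed=5)
        dt = res.death_times[0]
        assert (dt >= 1).all()
        mean = dt.mean()
        se = 2.0 / np.sqrt(len(dt))  # sd of Geometric(0.5) is sqrt(2)/1... ~1.41
        assert abs(mean - 2.0) < 4 * se


class TestReproducibility:
    def test_same_seed_same_cohort(self, net100, net100_b, frail_pair):
        pa, pb = frail_pair
        r1 = simulate_cohort(net100, net100_b, pa, pb, 100, max_steps=1500, master_seed=21)
        r2 = simulate_cohort(net100, net100_b, pa, pb, 100, max_steps=1500, master_seed=21)
        assert np.array_equal(r1.death_times, r2.death_times)
        assert np.array_equal(r1.f, r2.f)

    def test_trajectory_access(self, net100, net100_b, frail_pair):
        pa, pb = frail_pair
        res = simulate_cohort(net100, net100_b, pa, pb, 10, max_steps=1500, master_seed=21)
        traj = res[3]
        assert traj.a.f[0] == 100
        if traj.a.death_time is not None:
            assert traj.a.f[traj.a.death_time] < 10  # below the 10% threshold
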