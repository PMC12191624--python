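"""Prototype derivation, Metropolis-Hastings mechanics, and occupancy
distributions of the mutation sampler."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutsampler import (
    CausalNetwork,
    JointDistribution,
    NoPrototypesError,
    Parameterization,
    SamplerSettings,
    default_battery_32,
    derive_prototypes,
    joint_distribution,
    markov_violation_from_predictions,
    normative_predictions,
    occupancy_distribution,
    sampler_predictions,
    simulate_chain,
    start_distribution,
    transition_matrix,
)

from conftest import random_shared_params


def brute_force_prototypes(network):
    """Independent oracle: check every full assignment against every link."""
    out = []
    for s in itertools.product((0, 1), repeat=network.n):
        assign = dict(zip(network.variables, s))
        ok = True
        for a, b, pol in network.links:
            same = assign[a] == assign[b]
            if (pol == "generative") != same:
                ok = False
                break
        if ok:
            out.append("".join(map(str, s)))
    return set(out)


class TestPrototypes:
    def test_generative_diamond(self, diamond):
        assert set(derive_prototypes(diamond).as_strings()) == {"0000", "1111"}

    def test_inhibitory_diamonds_have_none(self, diamond_ya_inh, diamond_yb_inh):
        assert len(derive_prototypes(diamond_ya_inh)) == 0
        assert len(derive_prototypes(diamond_yb_inh)) == 0

    def test_geninh_common_cause(self):
        net = CausalNetwork(
            ("C", "EA", "EB"),
            (("C", "EA", "generative"), ("C", "EB", "inhibitory")),
        )
        assert set(derive_prototypes(net).as_strings()) == {"110", "001"}

    def test_all_inhibitory_common_cause(self):
        net = CausalNetwork(
            ("C", "EA", "EB"),
            (("C", "EA", "inhibitory"), ("C", "EB", "inhibitory")),
        )
        assert set(derive_prototypes(net).as_strings()) == {"100", "011"}

    def test_direction_ignored(self, common_cause, chain):
        # common cause and chain share prototypes: 000 and 111
        for net in (common_cause, chain):
            assert set(derive_prototypes(net).as_strings()) == {"000", "111"}

    def test_matches_bruteforce_on_all_fixtures(
        self, diamond, diamond_ya_inh, diamond_yb_inh, common_cause, chain, common_effect
    ):
        for net in (diamond, diamond_ya_inh, diamond_yb_inh, common_cause, chain, common_effect):
            assert set(derive_prototypes(net).as_strings()) == brute_force_prototypes(net)


class TestTransitionMatrix:
    def test_uniform_joint_moves_to_each_neighbor(self, diamond):
        joint = JointDistribution(diamond, np.full(16, 1 / 16))
        T = transition_matrix(joint)
        for s in range(16):
            for s2 in range(16):
                hamming = bin(s ^ s2).count("1")
                if hamming == 1:
                    assert T[s2, s] == pytest.approx(0.25)
                elif s != s2:
                    assert T[s2, s] == 0.0
            assert T[s, s] == pytest.approx(0.0)

    def test_mh_acceptance_ratio(self, diamond):
        """Asymmetric pair: uphill moves always accepted, downhill at the
        probability ratio."""
        probs = np.full(16, 1.0)
        probs[15] = 2.0  # state 1111 twice as probable as its neighbors
        probs /= probs.sum()
        T = transition_matrix(JointDistribution(diamond, probs))
        s_lo, s_hi = 7, 15  # Hamming-1 neighbors
        assert T[s_hi, s_lo] == pytest.approx(0.25 * 1.0)  # accept uphill
        assert T[s_lo, s_hi] == pytest.approx(0.25 * 0.5)  # accept w.p. 1/2

    def test_columns_are_distributions(self, diamond):
        rng = np.random.default_rng(0)
        joint = joint_distribution(diamond, random_shared_params(diamond, rng))
        T = transition_matrix(joint)
        assert np.all(T >= 0)
        np.testing.assert_allclose(T.sum(axis=0), 1.0, atol=1e-12)

    def test_stationarity_and_detailed_balance(self, diamond):
        rng = np.random.default_rng(12)
        for _ in range(100):
            pi = joint_distribution(diamond, random_shared_params(diamond, rng)).probs
            T = transition_matrix(JointDistribution(diamond, pi))
            np.testing.assert_allclose(T @ pi, pi, atol=1e-12)
            np.testing.assert_allclose(T * pi[None, :], (T * pi[None, :]).T, atol=1e-12)

    def test_rejects_zero_mass(self, diamond):
        probs = np.zeros(16)
        probs[0] = 1.0
        with pytest.raises(ValueError, match="strictly positive"):
            transition_matrix(JointDistribution(diamond, probs))


class TestOccupancy:
    def test_length_one_returns_start(self, diamond):
        rng = np.random.default_rng(1)
        joint = joint_distribution(diamond, random_shared_params(diamond, rng))
        T = transition_matrix(joint)
        start = np.zeros(16)
        start[3] = 1.0
        np.testing.assert_allclose(occupancy_distribution(T, start, 1.0), start)

    def test_two_step_hand_computation(self, diamond):
        """From a point mass on 0000 under the uniform joint, one uniform
        single-flip move: occupancy = 1/2 start + 1/8 on each neighbor."""
        T = transition_matrix(JointDistribution(diamond, np.full(16, 1 / 16)))
        start = np.zeros(16)
        start[0] = 1.0
        occ = occupancy_distribution(T, start, 2)
        expected = np.zeros(16)
        expected[0] = 0.5
        for i in range(4):
            expected[1 << i] = 0.125
        np.testing.assert_allclose(occ, expected, atol=1e-15)

    def test_interpolation_between_integer_lengths(self, diamond):
        rng = np.random.default_rng(2)
        joint = joint_distribution(diamond, random_shared_params(diamond, rng))
        T = transition_matrix(joint)
        start = np.full(16, 1 / 16)
        o3 = occupancy_distribution(T, start, 3)
        o4 = occupancy_distribution(T, start, 4)
        o35 = occupancy_distribution(T, start, 3.5)
        np.testing.assert_allclose(o35, 0.5 * o3 + 0.5 * o4, atol=1e-14)

    def test_converges_to_joint(self, diamond, group_params):
        joint = joint_distribution(diamond, group_params)
        T = transition_matrix(joint)
        start = np.zeros(16)
        start[0] = 1.0
        occ = occupancy_distribution(T, start, 10_000)
        tv = 0.5 * np.abs(occ - joint.probs).sum()
        assert tv < 0.01

    def test_longer_chains_closer_to_joint(self, diamond):
        rng = np.random.default_rng(9)
        for _ in range(10):
            joint = joint_distribution(diamond, random_shared_params(diamond, rng))
            T = transition_matrix(joint)
            start = np.zeros(16)
            start[0] = 1.0
            tv = lambda occ: 0.5 * np.abs(occ - joint.probs).sum()
            assert tv(occupancy_distribution(T, start, 1000)) < tv(
                occupancy_distribution(T, start, 4)
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lam=st.floats(min_value=1.0, max_value=60.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_occupancy_is_distribution(self, lam, seed):
        net = CausalNetwork(
            ("X", "YA", "YB", "Z"),
            (
                ("X", "YA", "generative"),
                ("X", "YB", "generative"),
                ("YA", "Z", "generative"),
                ("YB", "Z", "generative"),
            ),
        )
        rng = np.random.default_rng(seed)
        joint = joint_distribution(net, random_shared_params(net, rng))
        T = transition_matrix(joint)
        start = np.zeros(16)
        start[int(rng.integers(16))] = 1.0
        occ = occupancy_distribution(T, start, lam)
        assert np.all(occ >= 0)
        assert abs(occ.sum() - 1.0) < 1e-12

    def test_rejects_short_chains(self, diamond):
        T = transition_matrix(JointDistribution(diamond, np.full(16, 1 / 16)))
        with pytest.raises(ValueError):
            occupancy_distribution(T, np.full(16, 1 / 16), 0.5)


class TestSamplerPredictions:
    def test_lambda_one_is_pure_prototype_response(self, diamond, group_params):
        """At chain length 1 the occupancy is the half/half prototype mix:
        the marginal p(YA=1) is exactly 1/2, and conditioning on X=1 picks
        out the all-present prototype."""
        from mutsampler import Query

        settings_ = SamplerSettings(lambda_=1.0, start_mode="prototypes")
        queries = [Query("YA"), Query("YA", (("X", 1),))]
        preds = sampler_predictions(diamond, group_params, settings_, queries)
        assert preds[0] == pytest.approx(0.5)
        assert preds[1] == pytest.approx(1.0)

    def test_long_chain_approaches_normative(self, diamond, group_params, battery32):
        settings_ = SamplerSettings(lambda_=10_000, start_mode="uniform")
        preds = sampler_predictions(diamond, group_params, settings_, battery32)
        exact = normative_predictions(diamond, group_params, battery32)
        np.testing.assert_allclose(preds, exact, atol=1e-2)

    def test_prototype_mode_produces_positive_markov_score(self, diamond, group_params, battery32):
        settings_ = SamplerSettings(lambda_=17.0, start_mode="prototypes")
        preds = sampler_predictions(diamond, group_params, settings_, battery32)
        assert markov_violation_from_predictions(preds, battery32) > 0

    def test_empty_prototypes_error_directs_to_uniform(self, diamond_ya_inh):
        params = Parameterization.shared(diamond_ya_inh, 0.6, 0.5, 0.4, w_inh=-0.4)
        battery = default_battery_32(diamond_ya_inh)
        with pytest.raises(NoPrototypesError, match="uniform"):
            sampler_predictions(
                diamond_ya_inh, params, SamplerSettings(start_mode="prototypes"), battery
            )

    def test_uniform_start_distribution(self, diamond_ya_inh):
        start = start_distribution(diamond_ya_inh, SamplerSettings(start_mode="uniform"))
        np.testing.assert_allclose(start, 1 / 16)


class TestSimulateChain:
    def test_seed_reproducibility(self, diamond, group_params):
        s = SamplerSettings(lambda_=10, start_mode="prototypes")
        t1 = simulate_chain(diamond, group_params, s, 500, seed=42)
        t2 = simulate_chain(diamond, group_params, s, 500, seed=42)
        np.testing.assert_array_equal(t1, t2)

    def test_uniform_joint_visits_states_uniformly(self, diamond):
        params = Parameterization.shared(diamond, 0.5, 0.0, 0.0)
        s = SamplerSettings(start_mode="uniform")
        traj = simulate_chain(diamond, params, s, 100_000, seed=7)
        freqs = np.bincount(traj, minlength=16) / traj.size
        se = np.sqrt((1 / 16) * (15 / 16) / traj.size)
        # dependent samples inflate the error; allow a generous factor
        assert np.all(np.abs(freqs - 1 / 16) < 10 * se)

    def test_empirical_conditional_matches_exact(self, diamond, group_params):
        from mutsampler import Query, conditional_query

        joint = joint_distribution(diamond, group_params)
        exact = conditional_query(joint, Query("YA", (("X", 1),)))
        s = SamplerSettings(start_mode="uniform")
        traj = simulate_chain(diamond, group_params, s, 200_000, seed=3)
        states = diamond.states_matrix()[traj]
        x_on = states[:, 0] == 1
        emp = states[x_on, 1].mean()
        assert emp == pytest.approx(exact, abs=0.02)
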