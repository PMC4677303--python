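"""Fermi imitation, fixation probabilities and the embedded chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from agdyn import (
    PopulationSpec,
    beta_sweep,
    build_embedded_chain,
    fermi_imitation_probability,
    fixation_probability,
    stationary_distribution,
    summarize,
    transition_probabilities,
)


def fixation_oracle(f_A: float, f_B: float, N: int, beta: float) -> float:
    """Independent sum-of-products route: rho = 1 / sum_{i=0}^{N-1} gamma^i.

    Each product of T-/T+ ratios collapses to gamma^i with
    gamma = exp(-beta (f_A - f_B)); the sum is evaluated in the log domain.
    """
    log_gamma = -beta * (f_A - f_B)
    return float(np.exp(-logsumexp([i * log_gamma for i in range(N)])))


class TestFermiRule:
    def test_equal_payoffs_coin_flip(self):
        assert fermi_imitation_probability(3.0, 3.0, 17.0) == 0.5

    def test_neutral_limit(self):
        assert fermi_imitation_probability(1.0, 9.0, 0.0) == 0.5

    def test_strong_selection_is_deterministic(self):
        assert fermi_imitation_probability(0.0, 1.0, 100.0) == pytest.approx(
            1.0, abs=1e-10
        )
        assert fermi_imitation_probability(1.0, 0.0, 100.0) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_extreme_arguments_do_not_overflow(self):
        assert fermi_imitation_probability(0.0, 10.0, 1e5) == 1.0
        assert fermi_imitation_probability(10.0, 0.0, 1e5) == pytest.approx(
            0.0, abs=1e-300
        )

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            fermi_imitation_probability(1.0, 2.0, -0.1)


class TestTransitionProbabilities:
    def test_neutral_symmetry(self):
        # at beta=0 the Fermi factor is 1/2, leaving k(N-k)/(2N^2) each way
        for k in (1, 25, 99):
            t_plus, t_minus = transition_probabilities(k, 4.0, 7.0, 100, 0.0)
            assert t_plus == t_minus == pytest.approx(k * (100 - k) / (2 * 100**2))

    @pytest.mark.parametrize("k", [0, 100, -3])
    def test_absorbing_boundaries_rejected(self, k):
        with pytest.raises(ValueError):
            transition_probabilities(k, 1.0, 2.0, 100, 0.5)

    @given(
        k=st.integers(1, 49),
        f_A=st.floats(0, 10),
        f_B=st.floats(0, 10),
        beta=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_ratio_identity(self, k, f_A, f_B, beta):
        t_plus, t_minus = transition_probabilities(k, f_A, f_B, 50, beta)
        assert t_minus / t_plus == pytest.approx(
            math.exp(-beta * (f_A - f_B)), rel=1e-10
        )


class TestFixationProbability:
    def test_neutral_is_one_over_N(self):
        assert fixation_probability(4.0, 7.0, 100, 0.0) == 1.0 / 100

    def test_equal_payoffs_is_one_over_N(self):
        assert fixation_probability(5.0, 5.0, 37, 8.0) == pytest.approx(1 / 37)

    @given(
        f_A=st.floats(0, 10),
        f_B=st.floats(0, 10),
        beta=st.floats(0, 5),
        N=st.integers(2, 50),
    )
    @settings(max_examples=150, deadline=None)
    def test_closed_form_matches_product_formula(self, f_A, f_B, beta, N):
        got = fixation_probability(f_A, f_B, N, beta)
        want = fixation_oracle(f_A, f_B, N, beta)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    @given(f_A=st.floats(0, 10), f_B=st.floats(0, 10), beta=st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_two_player_population_reduces_to_fermi(self, f_A, f_B, beta):
        assert fixation_probability(f_A, f_B, 2, beta) == pytest.approx(
            fermi_imitation_probability(f_B, f_A, beta), rel=1e-12
        )

    def test_extreme_selection_saturates(self):
        assert fixation_probability(10.0, 0.0, 100, 500.0) == pytest.approx(1.0)
        assert fixation_probability(0.0, 10.0, 100, 500.0) == 0.0


class TestEmbeddedChain:
    def test_dg_state_count(self, dg_spec, dg_config):
        chain = build_embedded_chain(dg_spec, dg_config, beta=0.1)
        assert len(chain.states) == 10

    def test_restricted_ag_state_count(self, ag_spec, ag_restricted):
        chain = build_embedded_chain(ag_spec, ag_restricted, beta=0.1)
        assert len(chain.states) == 50

    def test_rows_sum_to_one(self, ag_spec, ag_restricted):
        chain = build_embedded_chain(ag_spec, ag_restricted, beta=2.0)
        np.testing.assert_allclose(chain.M.sum(axis=1), 1.0, atol=1e-12)

    def test_mutant_weight_split_does_not_change_stationary_law(
        self, ag_spec, ag_restricted
    ):
        # rescaling the dictator/receiver mutant weights only moves mass
        # to the diagonal, leaving the stationary distribution unchanged
        pi_half = stationary_distribution(
            build_embedded_chain(ag_spec, ag_restricted, 0.5, w_dictator=0.5)
        ).probs
        pi_skew = stationary_distribution(
            build_embedded_chain(ag_spec, ag_restricted, 0.5, w_dictator=0.3)
        ).probs
        np.testing.assert_allclose(pi_half, pi_skew, atol=1e-12)


class TestStationaryDistribution:
    def test_neutral_chain_is_uniform(self, ag_spec, ag_restricted):
        dist = stationary_distribution(
            build_embedded_chain(ag_spec, ag_restricted, beta=0.0)
        )
        np.testing.assert_allclose(dist.probs, 1.0 / 50, atol=1e-12)

    def test_near_neutral_within_total_variation(self, ag_spec, ag_restricted):
        dist = stationary_distribution(
            build_embedded_chain(ag_spec, ag_restricted, beta=1e-6)
        )
        tv = 0.5 * np.abs(dist.probs - 1.0 / len(dist.probs)).sum()
        assert tv < 1e-3

    @pytest.mark.parametrize("variant_fixture, p_star", [
        ("dg_config", 1),
        ("ag_restricted", 1),
        # with baseline expectation q0=2 the uninformed half of matchings
        # rejects a 1-ECU donation, so the smallest donation strong
        # selection can settle on in the noisy AG is 2 ECU
        ("noisy_ag_restricted", 2),
    ])
    def test_strong_selection_reaches_minimal_accepted_donation(
        self, variant_fixture, p_star, request
    ):
        cfg = request.getfixturevalue(variant_fixture)
        spec = PopulationSpec.from_config(cfg, N=100)
        for beta in (10.0, 50.0):
            dist = stationary_distribution(build_embedded_chain(spec, cfg, beta))
            assert dist.dictator_marginal[p_star] > 0.99

    def test_stationarity_residual(self, ag_spec, ag_restricted):
        for beta in (1e-4, 0.01, 1.0, 10.0):
            chain = build_embedded_chain(ag_spec, ag_restricted, beta)
            dist = stationary_distribution(chain)
            assert np.max(np.abs(dist.probs @ chain.M - dist.probs)) < 1e-10
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_marginals_consistent_with_joint(self, ag_spec, ag_restricted):
        dist = stationary_distribution(
            build_embedded_chain(ag_spec, ag_restricted, 0.2)
        )
        assert sum(dist.dictator_marginal.values()) == pytest.approx(1.0)
        assert sum(dist.receiver_marginal.values()) == pytest.approx(1.0)
        p_direct = {
            p: sum(w for s, w in zip(dist.states, dist.probs) if s.p == p)
            for p in {s.p for s in dist.states}
        }
        for p, w in dist.dictator_marginal.items():
            assert w == pytest.approx(p_direct[p])


class TestSummaries:
    def test_uniform_marginal_mean(self, dg_spec, dg_config):
        dist = stationary_distribution(build_embedded_chain(dg_spec, dg_config, 0.0))
        out = summarize(dist)
        assert out["mean_p"] == pytest.approx(5.5)
        assert out["mean_q"] is None

    def test_point_mass_mean(self, ag_spec, ag_restricted):
        dist = stationary_distribution(
            build_embedded_chain(ag_spec, ag_restricted, 20.0)
        )
        assert summarize(dist)["mean_p"] == pytest.approx(1.0, abs=1e-6)


def test_mean_strategies_decrease_with_selection(small_ag_spec, ag_restricted):
    table = beta_sweep(small_ag_spec, ag_restricted, np.logspace(-4, 1, 15))
    assert (np.diff(table["mean_p"]) <= 1e-9).all()
    assert (np.diff(table["mean_q"]) <= 1e-9).all()
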