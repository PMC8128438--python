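"""Closed-form belief-update equations and the effort optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import norm

from mcdcontrol.core import (
    Condition,
    MCDParams,
    TrialInputs,
    ValueBelief,
    certainty_gain,
    change_of_mind_prob,
    confidence_given_belief,
    evc,
    expected_abs_dmu,
    expected_confidence,
    expected_soa,
    optimal_effort_batch,
    optimize_z,
    posterior_variance,
    predict_trial,
    variance_abs_dmu,
)

MC_N = 400_000


def mc_ddelta(gamma, z, n=MC_N, seed=0):
    """Monte-Carlo draws of the mode-difference perturbation."""
    rng = np.random.default_rng(seed)
    return np.sqrt(2.0 * gamma * z) * rng.standard_normal(n)


class TestConfidence:
    @pytest.mark.parametrize(
        "dmu,s1,s2,expected",
        [
            (0.0, 1.0, 1.0, 0.5),
            (1.0, 0.5, 0.5, expit(np.pi / np.sqrt(3.0))),
            (-1.0, 0.5, 0.5, expit(np.pi / np.sqrt(3.0))),
        ],
    )
    def test_values(self, dmu, s1, s2, expected):
        assert confidence_given_belief(dmu, s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_moment_matching_close_to_gaussian_tail(self):
        # P(V1 > V2) for dmu=1, total variance 1 is Phi(1); the sigmoid
        # moment-matching approximation should land within 0.02 of it
        approx = confidence_given_belief(1.0, 0.5, 0.5)
        assert abs(approx - norm.cdf(1.0)) < 0.02

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            confidence_given_belief(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            confidence_given_belief(1.0, 1.0, -0.5)


class TestPosteriorVariance:
    @pytest.mark.parametrize(
        "sigma0,beta,z,expected",
        [(2.0, 1.5, 0.0, 2.0), (2.0, 0.0, 5.0, 2.0), (1.0, 1.0, 1.0, 0.5)],
    )
    def test_values(self, sigma0, beta, z, expected):
        assert posterior_variance(sigma0, beta, z) == pytest.approx(expected)

    @given(
        sigma0=st.floats(0.01, 50),
        beta=st.floats(0, 10),
        z=st.floats(0, 50),
    )
    @settings(deadline=None, max_examples=200)
    def test_precision_gain_identity(self, sigma0, beta, z):
        sig = posterior_variance(sigma0, beta, z)
        assert sig <= sigma0 + 1e-12
        assert 1.0 / sig - 1.0 / sigma0 == pytest.approx(beta * z, rel=1e-9, abs=1e-9)


class TestFoldedNormalMoments:
    def test_zero_effort_limits(self):
        assert expected_abs_dmu(-0.7, 1.3, 0.0) == 0.7
        assert expected_abs_dmu(0.4, 0.0, 2.0) == 0.4
        assert variance_abs_dmu(0.4, 1.3, 0.0) == 0.0

    def test_centered_closed_forms(self):
        # |X| with X ~ Normal(0, 2): mean 2/sqrt(pi), variance 2 - 4/pi
        assert expected_abs_dmu(0.0, 1.0, 1.0) == pytest.approx(2 / np.sqrt(np.pi), rel=1e-12)
        assert variance_abs_dmu(0.0, 1.0, 1.0) == pytest.approx(2 - 4 / np.pi, rel=1e-12)

    @pytest.mark.parametrize("dmu0,gamma,z", [(2.0, 0.5, 1.0), (0.3, 1.0, 0.7), (-1.2, 0.2, 3.0)])
    def test_against_monte_carlo(self, dmu0, gamma, z):
        # the closed form replaces the Gaussian CDF by a logistic sigmoid;
        # that approximation carries up to ~0.02 absolute error in the
        # shifted term, on top of pure Monte-Carlo error
        budget = 2 * abs(dmu0) * 0.025
        x = np.abs(dmu0 + mc_ddelta(gamma, z))
        se_mean = x.std(ddof=1) / np.sqrt(len(x))
        e_hat = expected_abs_dmu(dmu0, gamma, z)
        assert e_hat == pytest.approx(x.mean(), abs=3 * se_mean + budget)
        se_var = np.sqrt(2.0 / (len(x) - 1)) * x.var()
        assert variance_abs_dmu(dmu0, gamma, z) == pytest.approx(
            x.var(), abs=3 * se_var + 2 * x.mean() * budget
        )

    def test_exact_against_folded_normal_mean_with_true_cdf(self):
        # swapping the sigmoid for the exact Gaussian CDF must reproduce
        # the textbook folded-normal mean; the implementation then sits
        # within the documented approximation budget of it
        for dmu0, gamma, z in [(2.0, 0.5, 1.0), (0.3, 1.0, 0.7), (-1.2, 0.2, 3.0)]:
            v = 2.0 * gamma * z
            exact = np.sqrt(2 * v / np.pi) * np.exp(-(dmu0**2) / (2 * v)) + dmu0 * (
                1 - 2 * norm.cdf(-dmu0 / np.sqrt(v))
            )
            assert expected_abs_dmu(dmu0, gamma, z) == pytest.approx(
                exact, abs=2 * abs(dmu0) * 0.025
            )

    @given(dmu0=st.floats(-5, 5), gamma=st.floats(0, 5), z=st.floats(0, 10))
    @settings(deadline=None, max_examples=200)
    def test_moment_inequalities(self, dmu0, gamma, z):
        e1 = expected_abs_dmu(dmu0, gamma, z)
        # exact folded mean dominates |dmu0|; the sigmoid approximation
        # may undershoot it by its error budget
        assert e1 >= abs(dmu0) - 2 * abs(dmu0) * 0.025 - 1e-12
        assert variance_abs_dmu(dmu0, gamma, z) >= 0.0


class TestExpectedConfidence:
    def test_consistent_with_prior_confidence_at_zero_effort(self):
        for dmu0, s0 in [(0.3, 1.0), (-1.0, 2.5), (0.0, 0.5)]:
            assert expected_confidence(dmu0, s0, 1.0, 1.0, 0.0) == pytest.approx(
                confidence_given_belief(dmu0, s0, s0)
            )

    def test_strictly_increasing_in_effort(self):
        zs = np.array([0.0, 0.5, 1.0, 2.0, 5.0])
        pc = expected_confidence(1.0, 1.0, 1.0, 1.0, zs)
        assert np.all(np.diff(pc) > 0)

    def test_independent_reevaluation_of_composed_formula(self):
        # direct re-composition with scipy primitives, written separately
        # from the implementation path
        dmu0, s0, beta, gamma, z = 0.0, 1.0, 0.0, 1.0, 1.0
        e1 = 2 * np.sqrt(gamma * z / np.pi)  # folded mean at dmu0 = 0
        v1 = 2 * gamma * z - e1**2
        sig = 1.0 / (1.0 / s0 + beta * z)
        expected = 1.0 / (1.0 + np.exp(-np.pi * e1 / np.sqrt(6 * (sig + v1 / 2))))
        assert expected_confidence(dmu0, s0, beta, gamma, z) == pytest.approx(expected, rel=1e-12)


class TestChangeOfMindAndSoa:
    def test_structural_zeros(self):
        assert change_of_mind_prob(0.5, 0.0, 3.0) == 0.0
        assert change_of_mind_prob(0.5, 1.0, 0.0) == 0.0
        assert expected_soa(0.5, 0.0, 3.0) == 0.0
        assert expected_soa(0.5, 1.0, 0.0) == 0.0

    def test_symmetric_prior_gives_half(self):
        assert change_of_mind_prob(0.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_reversal_probability_against_monte_carlo(self):
        dd = mc_ddelta(1.0, 1.0)
        p_mc = np.mean(np.sign(1.0 + dd) != 1.0)
        # the sigmoid stand-in for the Gaussian tail peaks at ~0.024
        # absolute error near this argument
        assert abs(change_of_mind_prob(1.0, 1.0, 1.0) - p_mc) < 0.03

    def test_soa_against_monte_carlo_of_piecewise_definition(self):
        for dmu0 in (0.0, 1.0):
            dd = mc_ddelta(1.0, 1.0, seed=3)
            soa = np.where(dd > -dmu0, dd, -dd)
            se = soa.std(ddof=1) / np.sqrt(len(soa))
            assert expected_soa(dmu0, 1.0, 1.0) == pytest.approx(soa.mean(), abs=3 * se)

    @given(gamma=st.floats(0.001, 5), z=st.floats(0.001, 10),
           d1=st.floats(0, 3), d2=st.floats(0, 3))
    @settings(deadline=None, max_examples=200)
    def test_decreasing_in_prior_preference(self, gamma, z, d1, d2):
        lo, hi = sorted([d1, d2])
        assert change_of_mind_prob(hi, gamma, z) <= change_of_mind_prob(lo, gamma, z) + 1e-12
        assert expected_soa(hi, gamma, z) <= expected_soa(lo, gamma, z) + 1e-12
        assert change_of_mind_prob(hi, gamma, z) <= 0.5


class TestCertaintyGain:
    def test_values(self):
        assert certainty_gain(0.0, 5.0) == 0.0
        assert certainty_gain(2.0, 0.0) == 0.0
        assert certainty_gain(2.0, 3.0) == 6.0


class TestEvcAndOptimizer:
    params = MCDParams(alpha=0.05, beta=1.0, gamma=0.1, R=1.0, kR=2.0, kAlpha=0.3)

    def test_evc_at_zero(self):
        inputs = TrialInputs(0.3, 1.0)
        pc0 = expected_confidence(0.3, 1.0, self.params.beta, self.params.gamma, 0.0)
        assert evc(0.0, inputs, self.params) == pytest.approx(self.params.R * pc0)

    def test_condition_modifiers(self):
        inputs_c = TrialInputs(0.3, 1.0, Condition.CONSEQUENTIAL)
        inputs_p = TrialInputs(0.3, 1.0, Condition.PENALIZED)
        pc = expected_confidence(0.3, 1.0, self.params.beta, self.params.gamma, 1.0)
        assert evc(1.0, inputs_c, self.params) == pytest.approx(
            self.params.R * self.params.kR * pc - self.params.alpha
        )
        assert evc(1.0, inputs_p, self.params) == pytest.approx(
            self.params.R * pc - (self.params.alpha + self.params.kAlpha)
        )

    def test_no_benefit_means_no_effort(self):
        flat = MCDParams(alpha=0.1, beta=0.0, gamma=0.0)
        assert optimize_z(TrialInputs(0.3, 1.0), flat).z_opt == 0.0

    def test_prohibitive_cost_means_no_effort(self):
        costly = MCDParams(alpha=1e6, beta=1.0, gamma=1.0)
        assert optimize_z(TrialInputs(0.3, 1.0), costly).z_opt == 0.0

    def test_optimum_never_worse_than_zero_effort(self):
        inputs = TrialInputs(0.2, 2.0)
        alloc = optimize_z(inputs, self.params)
        assert alloc.evc_opt >= evc(0.0, inputs, self.params) - 1e-12

    def test_matches_brute_force_grid(self, rng):
        for _ in range(15):
            p = MCDParams(
                alpha=float(np.exp(rng.uniform(np.log(0.01), np.log(0.5)))),
                beta=float(np.exp(rng.uniform(np.log(0.05), np.log(5)))),
                gamma=float(np.exp(rng.uniform(np.log(0.005), np.log(1)))),
            )
            inputs = TrialInputs(float(rng.uniform(-1, 1)), float(rng.uniform(0.3, 5)))
            grid = np.linspace(0.0, 10.0, 100_001)
            values = p.R * expected_confidence(
                inputs.dmu0, inputs.sigma0, p.beta, p.gamma, grid
            ) - p.alpha * grid
            z_bf = grid[np.argmax(values)]
            with np.errstate(all="ignore"):
                z_hat = optimize_z(inputs, p, z_max=10.0).z_opt
            assert abs(z_hat - z_bf) <= 1e-4

    def test_truncation_warning(self):
        cheap = MCDParams(alpha=1e-9, beta=1.0, gamma=0.5)
        with pytest.warns(RuntimeWarning, match="z_max"):
            optimize_z(TrialInputs(0.1, 1.0), cheap, z_max=1.0)

    def test_batch_agrees_with_scalar(self, rng):
        dmu0 = rng.uniform(-1, 1, 12)
        sigma0 = rng.uniform(0.5, 4, 12)
        z_batch = optimal_effort_batch(
            dmu0, sigma0, np.ones(12), np.full(12, self.params.alpha),
            self.params.beta, self.params.gamma,
        )
        for i in range(12):
            z_scalar = optimize_z(TrialInputs(dmu0[i], sigma0[i]),
                                  MCDParams(self.params.alpha, self.params.beta, self.params.gamma)).z_opt
            assert abs(z_batch[i] - z_scalar) < 5e-3


class TestPredictTrial:
    def test_degenerate_efficacies(self):
        p = MCDParams(alpha=0.1, beta=0.0, gamma=0.0)
        pred = predict_trial(TrialInputs(0.4, 1.5), p)
        assert pred.z_opt == 0.0
        assert pred.q_change == 0.0
        assert pred.soa_expected == 0.0
        assert pred.certainty_gain == 0.0
        assert pred.confidence == pytest.approx(confidence_given_belief(0.4, 1.5, 1.5))

    def test_effort_nonincreasing_in_cost(self):
        zs = [
            predict_trial(TrialInputs(0.2, 1.5), MCDParams(alpha=a, beta=0.5, gamma=0.05)).z_opt
            for a in (0.01, 0.03, 0.1, 0.3, 1.0)
        ]
        assert all(z1 >= z2 - 1e-8 for z1, z2 in zip(zs, zs[1:]))

    def test_consequential_boosts_effort(self):
        p = MCDParams(alpha=0.05, beta=0.5, gamma=0.05, kR=2.0)
        z_n = predict_trial(TrialInputs(0.2, 1.5, Condition.NEUTRAL), p).z_opt
        z_c = predict_trial(TrialInputs(0.2, 1.5, Condition.CONSEQUENTIAL), p).z_opt
        assert z_c >= z_n

    def test_posterior_variance_never_exceeds_prior(self):
        p = MCDParams(alpha=0.02, beta=1.0, gamma=0.05)
        pred = predict_trial(TrialInputs(0.1, 3.0), p)
        assert pred.sigma_post <= 3.0


class TestDomainTypes:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ValueBelief(mu=0.0, sigma=0.0)
        with pytest.raises(ValueError):
            TrialInputs(dmu0=0.1, sigma0=-1.0)
        with pytest.raises(ValueError):
            MCDParams(alpha=0.0, beta=1.0, gamma=1.0)
        with pytest.raises(ValueError):
            MCDParams(alpha=0.1, beta=-0.1, gamma=1.0)

    def test_condition_coercion(self):
        assert TrialInputs(0.1, 1.0, "penalized").condition is Condition.PENALIZED
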