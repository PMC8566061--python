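import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fixmodal.multimodality import (
    EVIDENCE_CATEGORIES,
    DegenerateDataError,
    MixtureFit,
    MixturePrior,
    bayes_factor,
    classify_evidence,
    component_count,
    fit_mixture_rjmcmc,
    prior_odds_multimodal,
    sanitize_bf_cohort,
)
from fixmodal.synthetic import sample_mixture


def _fit(posterior_k, log_bf=0.0, bf=1.0, components=None):
    pk = np.asarray(posterior_k, float)
    return MixtureFit(
        k_draws=np.array([1]),
        posterior_k=pk,
        modal_k=int(np.argmax(pk)) + 1,
        components=components or [(0.0, 0.05, 1.0)],
        prior_odds=4.0,
        posterior_odds=float(pk[1:].sum() / pk[0]) if pk[0] else math.inf,
        bf=bf,
        log_bf=log_bf,
        category=classify_evidence(log_bf),
    )


class TestPriorOdds:
    def test_uniform_prior_is_four_analytically(self):
        assert prior_odds_multimodal(MixturePrior()) == pytest.approx(4.0)

    def test_simulation_agrees_with_analytic(self):
        a = prior_odds_multimodal(MixturePrior(), n_sim=10**5, seed=0)
        assert a == pytest.approx(4.0, abs=0.15)

    def test_two_point_prior(self):
        prior = MixturePrior(kmax=2, k_weights=[0.5, 0.5])
        assert prior_odds_multimodal(prior) == pytest.approx(1.0)

    @pytest.mark.parametrize("k_weights", [[1.0, 0.0], [0.0, 1.0]])
    def test_degenerate_priors_raise(self, k_weights):
        prior = MixturePrior(kmax=2, k_weights=k_weights)
        with pytest.raises(ZeroDivisionError):
            prior_odds_multimodal(prior)

    def test_small_n_sim_rejected(self):
        with pytest.raises(ValueError):
            prior_odds_multimodal(MixturePrior(), n_sim=100, seed=0)


class TestBayesFactor:
    def test_posterior_equal_to_prior_gives_one(self):
        bf, log_bf = bayes_factor(np.array([0.2, 0.2, 0.2, 0.2, 0.2]), a=4.0)
        assert bf == pytest.approx(1.0) and log_bf == pytest.approx(0.0)

    def test_tenfold_shift(self):
        # b = 40 against a = 4
        post = np.array([1 / 41, 40 / 41, 0, 0, 0])
        bf, log_bf = bayes_factor(post, a=4.0)
        assert bf == pytest.approx(10.0)
        assert log_bf == pytest.approx(math.log(10.0))

    def test_no_unimodal_draws_is_infinite(self):
        bf, log_bf = bayes_factor(np.array([0.0, 1.0, 0.0, 0.0, 0.0]), a=4.0)
        assert math.isinf(bf) and math.isinf(log_bf)

    def test_no_multimodal_draws_is_zero(self):
        bf, log_bf = bayes_factor(np.array([1.0, 0.0, 0.0, 0.0, 0.0]), a=4.0)
        assert bf == 0.0 and log_bf == -math.inf


class TestClassifyEvidence:
    @pytest.mark.parametrize(
        "log_bf,expected",
        [
            (0.5, "unimodal"),
            (1.0, "unimodal"),
            (2.0, "positive"),
            (3.0, "positive"),
            (4.0, "strong"),
            (5.0, "strong"),
            (6.0, "very_strong"),
            (-math.inf, "unimodal"),
            (math.inf, "very_strong"),
        ],
    )
    def test_thresholds(self, log_bf, expected):
        assert classify_evidence(log_bf) == expected

    @given(st.floats(allow_nan=False), st.floats(allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_log_bf(self, a, b):
        lo, hi = min(a, b), max(a, b)
        order = {c: i for i, c in enumerate(EVIDENCE_CATEGORIES)}
        assert order[classify_evidence(lo)] <= order[classify_evidence(hi)]


class TestSanitizeCohort:
    def test_zero_bf_replaced(self):
        fits = [_fit([1, 0, 0, 0, 0], bf=0.0, log_bf=-math.inf),
                _fit([0.1, 0.9, 0, 0, 0], bf=10.0, log_bf=math.log(10))]
        out = sanitize_bf_cohort(fits)
        assert out[0].bf == 0.003
        assert out[0].log_bf == pytest.approx(math.log(0.003))
        assert out[0].category == "unimodal"

    def test_infinite_log_bf_set_to_cohort_max(self):
        fits = [_fit([0, 1, 0, 0, 0], bf=math.inf, log_bf=math.inf),
                _fit([0.01, 0.99, 0, 0, 0], bf=math.exp(7.2), log_bf=7.2)]
        out = sanitize_bf_cohort(fits)
        assert out[0].log_bf == pytest.approx(7.2)
        assert out[1].log_bf == pytest.approx(7.2)

    def test_all_infinite_fall_back_to_cap(self):
        fits = [_fit([0, 1, 0, 0, 0], bf=math.inf, log_bf=math.inf)]
        out = sanitize_bf_cohort(fits)
        assert out[0].log_bf == 2.0e4

    def test_inputs_not_mutated(self):
        f = _fit([0, 1, 0, 0, 0], bf=math.inf, log_bf=math.inf)
        sanitize_bf_cohort([f])
        assert math.isinf(f.log_bf)


class TestComponentCount:
    @pytest.mark.parametrize(
        "pk,expected",
        [
            ([0.7, 0.3, 0, 0, 0], 1),
            ([0.2, 0.5, 0.3, 0, 0], 2),
            ([0.4, 0.4, 0.2, 0, 0], 1),  # tie -> smaller K
        ],
    )
    def test_modal_k(self, pk, expected):
        assert component_count(_fit(pk)) == expected


class TestFitMixture:
    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture_rjmcmc(np.zeros(5) + np.arange(5), seed=0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_mixture_rjmcmc(np.full(100, 0.3), seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            fit_mixture_rjmcmc(np.random.default_rng(0).normal(size=100), seed=None)

    def test_posterior_k_is_probability_vector(self):
        y = sample_mixture([(0.0, 0.05, 1.0)], 200, seed=11)
        fit = fit_mixture_rjmcmc(y, n_iter=300, burn_in=100, seed=12)
        assert fit.posterior_k.shape == (5,)
        assert fit.posterior_k.sum() == pytest.approx(1.0)
        assert len(fit.k_draws) == 300
        assert sum(w for _, _, w in fit.components) == pytest.approx(1.0, abs=1e-6)
        assert all(s > 0 for _, s, _ in fit.components)

    def test_same_seed_reproduces_chain(self):
        y = sample_mixture([(0.0, 0.05, 1.0)], 200, seed=21)
        f1 = fit_mixture_rjmcmc(y, n_iter=200, burn_in=50, seed=7)
        f2 = fit_mixture_rjmcmc(y, n_iter=200, burn_in=50, seed=7)
        np.testing.assert_array_equal(f1.k_draws, f2.k_draws)
        assert f1.components == f2.components

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_single_normal_found_unimodal(self, seed):
        y = sample_mixture([(0.0, 0.05, 1.0)], 500, seed=seed)
        fit = fit_mixture_rjmcmc(y, seed=seed + 1)
        assert fit.modal_k == 1
        assert fit.posterior_k[0] > 0.5

    @pytest.mark.parametrize("seed", [404, 505, 606])
    def test_separated_bimodal_recovered(self, seed):
        true = [(-0.15, 0.03, 0.5), (0.15, 0.03, 0.5)]
        y = sample_mixture(true, 500, seed=seed)
        fit = fit_mixture_rjmcmc(y, seed=seed + 1)
        assert fit.modal_k == 2
        means = sorted(m for m, _, _ in fit.components)
        assert means[0] == pytest.approx(-0.15, abs=0.02)
        assert means[1] == pytest.approx(0.15, abs=0.02)
        assert fit.log_bf > 5.0

    def test_component_means_ascending(self):
        y = sample_mixture([(-0.2, 0.03, 0.5), (0.2, 0.03, 0.5)], 400, seed=31)
        fit = fit_mixture_rjmcmc(y, n_iter=500, burn_in=200, seed=32)
        means = [m for m, _, _ in fit.components]
        assert means == sorted(means)
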