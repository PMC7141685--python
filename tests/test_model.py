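"""Capture-recapture likelihood, sampler and posterior summaries."""

import math

import numpy as np
import pytest
from scipy.stats import binom, poisson

from frdd.model import (
    CaptureRecaptureModel,
    CRObservations,
    CRParameters,
    CRPriorSet,
    available_marked,
    log_posterior,
    summarize_posterior,
    unmarked_count_log_pmf,
)
from frdd.priors import (
    DiscreteUniformPrior,
    GammaRatioPrior,
    LogNormalPrior,
    MarkingSummary,
    UniformPrior,
)


def convolution_oracle(k, n, q, lam, b_max=200):
    """Independent route: numerically convolve full binomial and Poisson
    pmf vectors with numpy."""
    a = np.arange(0, n + 1)
    b = np.arange(0, b_max + 1)
    pmf = np.convolve(binom.pmf(a, n, q), poisson.pmf(b, lam))
    return pmf[k] if k < pmf.size else 0.0


class TestUnmarkedCountPmf:
    def test_empty_village_sees_nothing(self):
        assert unmarked_count_log_pmf(0, 0, 0.7, 0.0) == 0.0

    def test_reduces_to_binomial_without_ownerless(self):
        assert unmarked_count_log_pmf(2, 2, 0.5, 0.0) == pytest.approx(math.log(0.25))
        assert unmarked_count_log_pmf(3, 2, 0.5, 0.0) == -math.inf

    @pytest.mark.parametrize(
        "k,n,q,lam",
        [(0, 5, 0.3, 0.7), (4, 10, 0.45, 1.2), (12, 8, 0.9, 6.0),
         (25, 60, 0.35, 0.01), (3, 0, 0.5, 2.5)],
    )
    def test_matches_numerical_convolution(self, k, n, q, lam):
        expected = convolution_oracle(k, n, q, lam)
        assert math.exp(unmarked_count_log_pmf(k, n, q, lam)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_distribution_normalises(self):
        total = sum(
            math.exp(unmarked_count_log_pmf(k, 6, 0.4, 1.1)) for k in range(80)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize(
        "kwargs", [dict(k=-1, n_owned_unmarked=3, q_owned=0.5, lambda_detect=1),
                   dict(k=1, n_owned_unmarked=-2, q_owned=0.5, lambda_detect=1),
                   dict(k=1, n_owned_unmarked=3, q_owned=1.5, lambda_detect=1),
                   dict(k=1, n_owned_unmarked=3, q_owned=0.5, lambda_detect=-1)],
    )
    def test_precondition_violations(self, kwargs):
        with pytest.raises(ValueError):
            unmarked_count_log_pmf(**kwargs)


def _point_priors(p_low, p_high, owned_low, owned_high,
                  mu=-30.0, tau=100.0, c_low=0.0, c_high=0.0):
    return CRPriorSet(
        recapture=UniformPrior(p_low, p_high),
        confinement=UniformPrior(c_low, c_high),
        ratio=LogNormalPrior(mu, tau),
        owned=DiscreteUniformPrior(owned_low, owned_high),
    )


class TestLogPosterior:
    def test_outside_prior_support_is_impossible(self):
        obs = CRObservations(MarkingSummary(2, 0, 1), (1,), (0,))
        priors = _point_priors(0.4, 0.8, 2, 10)
        params = CRParameters(p=0.95, c=0.0, r=1e-13, n_owned=2)
        assert log_posterior(params, obs, priors) == -math.inf

    def test_single_transect_binomial_term(self):
        """With c=0, r->0 and one transect the data likelihood is just the
        marked binomial: C(2,1) 0.5^2 = 0.5."""
        obs = CRObservations(MarkingSummary(2, 0, 1), (1,), (0,))
        model = CaptureRecaptureModel(obs, _point_priors(0.0, 1.0, 2, 10))
        ll = model.loglike(CRParameters(p=0.5, c=0.0, r=1e-300, n_owned=2))
        assert ll == pytest.approx(math.log(0.5))

    def test_more_marked_seen_than_collars_left(self):
        """Collar loss shrinks the marked pool: seeing all Mc marked dogs
        on a late transect is impossible once a collar was lost."""
        marking = MarkingSummary(10, 5, 2)
        assert available_marked(marking)[1] < 10
        obs = CRObservations(marking, (3, 10), (0, 0))
        params = CRParameters(p=0.5, c=0.0, r=1e-13, n_owned=20)
        assert log_posterior(params, obs, _point_priors(0, 1, 10, 40)) == -math.inf
        with pytest.raises(ValueError, match="marked counts exceed"):
            CaptureRecaptureModel(obs, _point_priors(0, 1, 10, 40))

    def test_transect_exchange_invariance_without_collar_loss(self):
        """With Ml=0 the collar-loss schedule is flat, so transect labels
        carry no information and any reordering keeps the density."""
        marking = MarkingSummary(30, 0, 3)
        priors = _point_priors(0.0, 1.0, 30, 200, mu=-2.0, tau=2.0)
        params = CRParameters(p=0.5, c=0.1, r=0.05, n_owned=80)
        base = log_posterior(
            CRParameters(**vars(params)),
            CRObservations(marking, (10, 14, 7), (20, 25, 13)), priors)
        swapped = log_posterior(
            params, CRObservations(marking, (7, 10, 14), (13, 20, 25)), priors)
        assert swapped == pytest.approx(base)

    def test_available_marked_rounds_half_up(self):
        # Mc=61, Ml=3, T=4: lm = 3/61 * t/4, M_t = round(61 - 3t/4)
        M = available_marked(MarkingSummary(61, 3, 4))
        assert list(M) == [60, 60, 59, 58]


class TestSampler:
    def test_seed_reproducibility(self, survey, survey_priors):
        model = CaptureRecaptureModel(survey.observations, survey_priors)
        a = model.fit(n_chains=2, n_iter=1500, n_burn=500, seed=9)
        b = model.fit(n_chains=2, n_iter=1500, n_burn=500, seed=9)
        for key in a.draws:
            np.testing.assert_array_equal(a.draws[key], b.draws[key])

    def test_seed_required(self, survey, survey_priors):
        model = CaptureRecaptureModel(survey.observations, survey_priors)
        with pytest.raises(ValueError, match="seed"):
            model.fit(n_chains=1, n_iter=100, n_burn=10)

    def test_recovers_generative_truth(self, survey, fitted):
        lo, hi = np.percentile(fitted.draws["n_owned"], [2.5, 97.5])
        assert lo <= survey.truth["n_owned"] <= hi
        assert fitted.posterior_summary().owned.mean == pytest.approx(
            survey.truth["n_owned"], rel=0.15
        )

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_degenerate_perfect_detection_pins_population(self):
        """p=1, c=0, no ownerless, every dog marked and always resighted:
        any owned count above Mc would force unmarked sightings, so the
        posterior collapses onto N_o = Mc."""
        marking = MarkingSummary(25, 0, 3)
        obs = CRObservations(marking, (25, 25, 25), (0, 0, 0))
        priors = _point_priors(1.0, 1.0, 25, 60)
        res = CaptureRecaptureModel(obs, priors).fit(
            n_chains=1, n_iter=1200, n_burn=200, seed=4
        )
        assert set(np.unique(res.draws["n_owned"])) == {25}

    def test_diagnostics_and_summary_table(self, fitted):
        table = fitted.summary()
        assert {"p", "c", "r", "n_owned", "lambda_u", "total"} <= set(table.index)
        assert table.loc["n_owned", "r_hat"] < 1.05
        assert table.loc["n_owned", "ess"] > 100


class TestSummaries:
    def test_constant_draws_round_half_up(self):
        draws = {"n_owned": np.full(1200, 100.0), "lambda_u": np.full(1200, 0.5)}
        report = summarize_posterior(draws).as_report()
        assert report["owned"] == {"mean": 100, "cri_low": 100, "cri_high": 100}
        assert report["total"] == {"mean": 101, "cri_low": 101, "cri_high": 101}

    def test_uniform_grid_percentiles(self):
        draws = {"n_owned": np.arange(1, 1001, dtype=float),
                 "lambda_u": np.zeros(1000)}
        summ = summarize_posterior(draws)
        assert summ.owned.mean == pytest.approx(500.5)
        assert summ.owned.cri_low == pytest.approx(25.975)
        assert summ.owned.cri_high == pytest.approx(975.025)

    def test_against_sort_based_oracle(self, rng):
        x = rng.gamma(3.0, 50.0, size=5000)
        lam = rng.exponential(0.2, size=5000)
        summ = summarize_posterior({"n_owned": x, "lambda_u": lam})
        xs = np.sort(x + lam)
        # linear-interpolation percentile, computed by hand from the sorted vector
        def pct(v, q):
            pos = q / 100 * (v.size - 1)
            i = int(pos)
            return v[i] + (pos - i) * (v[i + 1] - v[i])
        assert summ.total.mean == pytest.approx((x + lam).mean())
        assert summ.total.cri_low == pytest.approx(pct(xs, 2.5))
        assert summ.total.cri_high == pytest.approx(pct(xs, 97.5))

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_posterior({"n_owned": np.array([]), "lambda_u": np.array([])})

    def test_lambda_derived_from_ratio_when_missing(self):
        summ = summarize_posterior({"n_owned": np.full(1000, 80.0),
                                    "r": np.full(1000, 0.01)})
        assert summ.ownerless.mean == pytest.approx(0.8)


@pytest.fixture(scope="session")
def shifts(survey, survey_priors):
    model = CaptureRecaptureModel(survey.observations, survey_priors)
    conf = survey_priors.confinement
    return model.prior_sensitivity(
        {
            "identity": {},
            "wide_confinement": {
                "confinement": UniformPrior(conf.low, min(1.0, conf.high + 0.25))
            },
            "gamma_ratio": {"ratio": GammaRatioPrior(1.0, 10.0)},
        },
        n_chains=2, n_iter=5000, n_burn=1500, seed=3,
    )


class TestPriorSensitivity:
    def test_identity_perturbation_is_exact_noop(self, shifts):
        assert shifts.loc["identity"].abs().max() == 0.0

    def test_widening_confinement_barely_moves_estimates(self, shifts):
        assert shifts.loc["wide_confinement", "total_pct_change"] == pytest.approx(
            0.0, abs=5.0
        )

    def test_gamma_ratio_moves_split_more_than_total(self, shifts):
        row = shifts.loc["gamma_ratio"]
        assert abs(row["total_pct_change"]) <= max(
            abs(row["owned_pct_change"]), abs(row["ownerless_pct_change"])
        ) + 1e-9

    def test_invalid_perturbation_rejected(self, survey, survey_priors):
        model = CaptureRecaptureModel(survey.observations, survey_priors)
        with pytest.raises(ValueError, match="unknown prior component"):
            model.prior_sensitivity({"bad": {"detection": UniformPrior(0, 1)}})
        with pytest.raises(ValueError, match="expects"):
            model.prior_sensitivity({"bad": {"ratio": UniformPrior(0, 1)}})
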