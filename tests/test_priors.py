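"""Prior elicitation: recapture/confinement bounds, ratio fit, collar loss."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frdd.priors import (
    DiscreteUniformPrior,
    LogNormalPrior,
    MarkingSummary,
    UniformPrior,
    collar_loss_probability,
    confinement_prior,
    fit_ownerless_ratio_prior,
    owned_count_prior,
    recapture_prior,
)


class TestRecapturePrior:
    @pytest.mark.parametrize(
        "components, expected",
        [
            # published site bounds: coverage x encountering x recording
            ((0.44, 1.00, 0.70, 0.90, 0.90, 0.99), (0.28, 0.89)),
            ((0.23, 0.80, 0.70, 0.90, 0.90, 0.99), (0.14, 0.71)),
            ((1, 1, 1, 1, 1, 1), (1.00, 1.00)),
        ],
    )
    def test_component_products(self, components, expected):
        prior = recapture_prior(*components)
        assert (prior.low, prior.high) == expected

    def test_full_precision_when_unrounded(self):
        prior = recapture_prior(0.44, 1.00, 0.70, 0.90, 0.90, 0.99,
                                report_decimals=None)
        assert prior.low == pytest.approx(0.44 * 0.70 * 0.90)
        assert prior.high == pytest.approx(0.90 * 0.99)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.2), (0.8, 0.2)])
    def test_invalid_component_named_in_error(self, bad):
        with pytest.raises(ValueError, match="encounter"):
            recapture_prior(0.4, 0.9, bad[0], bad[1], 0.9, 0.99)

    @given(
        mins=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        bumps=st.lists(st.floats(0, 1), min_size=3, max_size=3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_each_component(self, mins, bumps):
        """Raising any component minimum never lowers the prior's low bound."""
        maxs = [1.0, 1.0, 1.0]
        base = recapture_prior(mins[0], maxs[0], mins[1], maxs[1],
                               mins[2], maxs[2], report_decimals=None)
        for i in range(3):
            raised = list(mins)
            raised[i] = min(1.0, raised[i] + bumps[i] * (1 - raised[i]))
            moved = recapture_prior(raised[0], maxs[0], raised[1], maxs[1],
                                    raised[2], maxs[2], report_decimals=None)
            assert moved.low >= base.low - 1e-12


class TestConfinementPrior:
    def test_always_roaming_dogs_are_never_confined(self):
        assert confinement_prior({"always": 30}) == UniformPrior(0.0, 0.0)

    def test_never_roaming_dogs_are_always_confined(self):
        assert confinement_prior({"never": 7}) == UniformPrior(1.0, 1.0)

    def test_count_weighted_means(self):
        prior = confinement_prior({"always": 50, "day_only": 10, "never": 5})
        assert prior.low == pytest.approx(5 / 65)
        assert prior.high == pytest.approx((10 * 0.25 + 5) / 65)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="no dogs to weight"):
            confinement_prior({"always": 0, "never": 0})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confinement_prior({"weekends_only": 3})

    @given(
        counts=st.fixed_dictionaries({
            "never": st.integers(0, 50),
            "always": st.integers(0, 50),
            "day_only": st.integers(0, 50),
            "night_only": st.integers(0, 50),
            "few_hours": st.integers(0, 50),
        }).filter(lambda d: sum(d.values()) > 0),
        scale=st.integers(1, 7),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds_ordered_and_scale_invariant(self, counts, scale):
        prior = confinement_prior(counts)
        assert 0.0 <= prior.low <= prior.high <= 1.0
        scaled = confinement_prior({k: v * scale for k, v in counts.items()})
        assert scaled.low == pytest.approx(prior.low)
        assert scaled.high == pytest.approx(prior.high)


class TestOwnerlessRatioPrior:
    def test_zero_variance_ratios_hit_the_precision_cap(self):
        r = math.exp(-2)
        prior = fit_ownerless_ratio_prior([1, 1, 1], [r, r, r], tau_cap=1e6)
        assert prior.mu == pytest.approx(-2)
        assert prior.tau == 1e6

    def test_known_log_ratios(self):
        ownerless = [math.exp(-1), math.exp(-2), math.exp(-3)]
        prior = fit_ownerless_ratio_prior([1, 1, 1], ownerless)
        assert prior.mu == pytest.approx(-2.0)
        assert prior.tau == pytest.approx(1.0)  # unbiased var of {-1,-2,-3}

    def test_zero_estimates_excluded_before_fit(self):
        prior = fit_ownerless_ratio_prior([10, 10, 10], [0, 1, 1])
        assert prior.mu == pytest.approx(math.log(0.1))
        assert prior.tau == 1e6  # two identical surviving ratios

    def test_too_few_usable_ratios_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_ownerless_ratio_prior([10, 10], [0, 1])

    def test_parameter_recovery_from_lognormal_samples(self, rng):
        mu_true, tau_true = -1.5, 2.0
        ratios = np.exp(rng.normal(mu_true, tau_true ** -0.5, size=5000))
        prior = fit_ownerless_ratio_prior(np.ones(5000), ratios)
        assert prior.mu == pytest.approx(mu_true, rel=0.05)
        assert prior.tau == pytest.approx(tau_true, rel=0.05)


class TestCollarLoss:
    def test_final_transect_fraction(self):
        marking = MarkingSummary(n_collared=61, n_lost=3, n_transects=4)
        assert collar_loss_probability(marking, 4) == pytest.approx(3 / 61)

    def test_no_losses_means_zero_everywhere(self):
        marking = MarkingSummary(50, 0, 4)
        assert all(collar_loss_probability(marking, t) == 0.0 for t in range(1, 5))

    def test_total_loss_reaches_one(self):
        marking = MarkingSummary(10, 10, 3)
        assert collar_loss_probability(marking, 3) == 1.0

    def test_no_marked_dogs_convention(self):
        assert collar_loss_probability(MarkingSummary(0, 0, 2), 1) == 0.0

    @pytest.mark.parametrize("t", [0, 5, -1])
    def test_transect_index_bounds(self, t):
        with pytest.raises(ValueError):
            collar_loss_probability(MarkingSummary(61, 3, 4), t)

    @given(mc=st.integers(1, 300), ml_frac=st.floats(0, 1), T=st.integers(1, 10))
    @settings(max_examples=100, derandomize=True)
    def test_linear_and_nondecreasing_in_t(self, mc, ml_frac, T):
        ml = int(ml_frac * mc)
        marking = MarkingSummary(mc, ml, T)
        vals = [collar_loss_probability(marking, t) for t in range(1, T + 1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(ml / mc)
        # linear in t/T: lm(t) = t * lm(1)
        assert all(v == pytest.approx((i + 1) * vals[0]) for i, v in enumerate(vals))


class TestOwnedCountPrior:
    def test_defaults_to_collared_through_cap(self):
        assert owned_count_prior(61) == DiscreteUniformPrior(61, 1000)
        assert owned_count_prior(125, 1000) == DiscreteUniformPrior(125, 1000)

    def test_degenerate_zero(self):
        assert owned_count_prior(0, 0) == DiscreteUniformPrior(0, 0)

    def test_cap_below_marked_rejected(self):
        with pytest.raises(ValueError):
            owned_count_prior(100, 50)


class TestContainers:
    def test_marking_summary_invariants(self):
        with pytest.raises(ValueError):
            MarkingSummary(n_collared=5, n_lost=6, n_transects=4)
        with pytest.raises(ValueError):
            MarkingSummary(n_collared=5, n_lost=0, n_transects=0)

    def test_uniform_prior_invariants(self):
        with pytest.raises(ValueError):
            UniformPrior(0.5, 0.4)
        with pytest.raises(ValueError):
            UniformPrior(-0.1, 0.4)

    def test_lognormal_mean_uses_precision(self):
        prior = LogNormalPrior(mu=-6.57, tau=5.24)
        assert prior.mean == pytest.approx(math.exp(-6.57 + 0.5 / 5.24))
        with pytest.raises(ValueError):
            LogNormalPrior(0.0, 0.0)
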