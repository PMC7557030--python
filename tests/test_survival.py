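"""Survival primitives: KM, pseudo-IPD reconstruction, Weibull MLE,
per-cycle transition probabilities, and moment-matched distributions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import WeibullFitter

from hlcea.survival import (
    EventTable,
    KMPublication,
    WeibullFit,
    WeibullFitError,
    beta_from_moments,
    fit_weibull_mle,
    gamma_from_moments,
    km_estimate,
    km_survival_at,
    reconstruct_ipd,
    transition_prob,
    tp_standard_error,
    weibull_survival,
)
from hlcea.synthetic import CohortSpec, generate_cohort


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(EventTable([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0]))
        assert np.all(km[:, 1] == 1.0)

    def test_two_events_product_limit(self):
        km = km_estimate(EventTable([1.0, 2.0], [1, 1]))
        assert km_survival_at(km, 0.5) == pytest.approx(1.0)
        assert km_survival_at(km, 1.5) == pytest.approx(0.5)
        assert km_survival_at(km, 2.0) == pytest.approx(0.0)

    def test_censoring_rescales_risk_set(self):
        # event at 1 (3 at risk), censor at 1.5, event at 3 (1 at risk):
        # S(1) = 2/3 and S(3) = 2/3 * (1 - 1/1) = 0 — the censored subject
        # leaves the risk set before the final event.
        km = km_estimate(EventTable([1.0, 1.5, 3.0], [1, 0, 1]))
        assert km_survival_at(km, 1.0) == pytest.approx(2.0 / 3.0)
        assert km_survival_at(km, 2.0) == pytest.approx(2.0 / 3.0)
        assert km_survival_at(km, 3.0) == pytest.approx(0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            EventTable([], [])

    def test_curve_starts_at_one_and_never_increases(self):
        table = generate_cohort(CohortSpec(n=100, seed=3))
        km = km_estimate(table)
        assert km[0, 0] == 0.0 and km[0, 1] == 1.0
        assert np.all(np.diff(km[:, 1]) <= 0)


class TestReconstructIPD:
    def test_half_survival_gives_half_events(self):
        pub = KMPublication([(0, 1.0), (6, 0.5)], [(0, 10), (6, 5)], 10)
        table = reconstruct_ipd(pub)
        assert table.n == 10
        assert np.sum(table.event[(table.time > 0) & (table.time <= 6)]) == 5

    def test_flat_curve_gives_no_events(self):
        pub = KMPublication([(0, 1.0), (12, 1.0)], [(0, 8), (12, 8)], 8)
        table = reconstruct_ipd(pub)
        assert table.n_events == 0
        assert np.all(table.time == 12.0)

    def test_interval_wise_event_counts(self):
        pub = KMPublication(
            [(0, 1.0), (6, 0.8), (12, 0.4)], [(0, 10), (6, 8), (12, 4)], 10
        )
        table = reconstruct_ipd(pub)
        first = np.sum(table.event[(table.time > 0) & (table.time <= 6)])
        second = np.sum(table.event[(table.time > 6) & (table.time <= 12)])
        assert (first, second) == (2, 4)

    def test_increasing_survival_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            KMPublication([(0, 1.0), (6, 0.5), (12, 0.7)], [(0, 10)], 10)

    def test_risk_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="total_n"):
            KMPublication([(0, 1.0), (6, 0.5)], [(0, 12)], 10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_km_round_trips_published_coordinates(self, seed):
        from hlcea.synthetic import PublicationSpec, generate_km_publication

        pub = generate_km_publication(PublicationSpec(n=664, seed=seed))
        table = reconstruct_ipd(pub)
        km = km_estimate(table)
        recon = km_survival_at(km, pub.coords[:, 0])
        assert np.max(np.abs(recon - pub.coords[:, 1])) <= 1.0 / pub.total_n


class TestWeibullMLE:
    def test_parameter_recovery_uncensored(self):
        table = generate_cohort(
            CohortSpec(n=2000, shape=1.0, scale=24.0, censor_rate=0.0,
                       admin_horizon_months=1e9, seed=42)
        )
        fit = fit_weibull_mle(table)
        assert 0.9 <= fit.shape <= 1.1
        assert 22.0 <= fit.scale <= 26.0

    def test_parameter_recovery_with_censoring(self):
        table = generate_cohort(
            CohortSpec(n=2000, shape=1.5, scale=36.0, censor_rate=0.2,
                       admin_horizon_months=1e9, seed=7)
        )
        fit = fit_weibull_mle(table)
        se = np.sqrt(np.diag(fit.cov_log))
        z = np.abs(np.log([fit.shape, fit.scale]) - np.log([1.5, 36.0])) / se
        assert np.all(z < 3.0)

    def test_exponential_data_recovers_unit_shape(self):
        table = generate_cohort(
            CohortSpec(n=5000, shape=1.0, scale=30.0, censor_rate=0.0,
                       admin_horizon_months=1e9, seed=11)
        )
        fit = fit_weibull_mle(table)
        assert abs(fit.shape - 1.0) < 0.05

    def test_all_censored_input_rejected(self):
        with pytest.raises(WeibullFitError, match="events"):
            fit_weibull_mle(EventTable([5.0, 6.0, 7.0], [0, 0, 0]))

    def test_matches_lifelines_reference_fit(self):
        """Independent cross-check against lifelines' Weibull fitter."""
        table = generate_cohort(CohortSpec(n=800, seed=19))
        ours = fit_weibull_mle(table)
        wf = WeibullFitter().fit(table.time, table.event)
        assert ours.scale == pytest.approx(wf.lambda_, rel=1e-4)
        assert ours.shape == pytest.approx(wf.rho_, rel=1e-4)


class TestCurveEvaluation:
    def test_survival_closed_forms(self):
        fit = WeibullFit(2.0, 10.0)
        assert weibull_survival(fit, 0.0) == pytest.approx(1.0)
        assert weibull_survival(fit, 10.0) == pytest.approx(np.exp(-1.0))
        assert weibull_survival(WeibullFit(1.0, 10.0), 5.0) == pytest.approx(
            np.exp(-0.5)
        )
        with pytest.raises(ValueError):
            weibull_survival(fit, -1.0)

    def test_transition_prob_constant_hazard_is_time_invariant(self):
        fit = WeibullFit(1.0, 12.0)
        expected = 1.0 - np.exp(-0.5)
        for t in (0.0, 6.0, 60.0, 179.0):
            assert transition_prob(fit, t, 6.0) == pytest.approx(expected)

    def test_transition_prob_vanishes_with_cycle_length(self):
        fit = WeibullFit(1.5, 24.0)
        assert transition_prob(fit, 12.0, 1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_increasing_hazard_raises_later_cycle_risk(self):
        fit = WeibullFit(2.0, 12.0)
        assert transition_prob(fit, 12.0, 6.0) > transition_prob(fit, 0.0, 6.0)

    @given(
        shape=st.floats(0.3, 5.0),
        scale=st.floats(1.0, 600.0),
        cycle_index=st.integers(0, 30),
    )
    def test_transition_prob_is_a_probability(self, shape, scale, cycle_index):
        p = transition_prob(WeibullFit(shape, scale), cycle_index * 6.0, 6.0)
        assert 0.0 <= p <= 1.0


class TestTransitionSE:
    COV = np.array([[0.0025, -0.002], [-0.002, 0.01]])

    def test_zero_covariance_gives_zero_se(self):
        assert tp_standard_error(WeibullFit(0.75, 600.0), 24.0, 6.0) == 0.0

    def test_agrees_with_parametric_bootstrap(self):
        fit = WeibullFit(0.75, 600.0, self.COV)
        se = tp_standard_error(fit, 24.0, 6.0)
        rng = np.random.default_rng(11)
        draws = rng.multivariate_normal(np.log([0.75, 600.0]), self.COV, size=10_000)
        ps = [
            transition_prob(WeibullFit(np.exp(a), np.exp(b)), 24.0, 6.0)
            for a, b in draws
        ]
        assert se == pytest.approx(np.std(ps), rel=0.15)

    def test_se_scales_as_sqrt_of_covariance(self):
        base = tp_standard_error(WeibullFit(0.75, 600.0, self.COV), 24.0, 6.0)
        small = tp_standard_error(
            WeibullFit(0.75, 600.0, self.COV * 1e-4), 24.0, 6.0
        )
        assert small / base == pytest.approx(1e-2, rel=1e-3)


class TestMomentMatching:
    def test_beta_uniform_special_case(self):
        a, b = beta_from_moments(0.5, np.sqrt(1.0 / 12.0))
        assert (a, b) == pytest.approx((1.0, 1.0))

    def test_beta_symmetric_case(self):
        a, b = beta_from_moments(0.5, np.sqrt(0.05))
        assert (a, b) == pytest.approx((2.0, 2.0))

    def test_beta_small_se_concentrates_at_mean(self):
        a, b = beta_from_moments(0.3, 1e-4)
        rng = np.random.default_rng(0)
        draws = rng.beta(a, b, size=1000)
        assert np.max(np.abs(draws - 0.3)) < 1e-3

    def test_beta_rejects_invalid_mean(self):
        with pytest.raises(ValueError):
            beta_from_moments(1.2, 0.1)

    def test_gamma_exponential_special_case(self):
        assert gamma_from_moments(1.0, 1.0) == pytest.approx((1.0, 1.0))

    def test_gamma_regimen_cost_closed_form(self):
        shape, rate = gamma_from_moments(116_160.0, 23_232.0)
        assert shape == pytest.approx(25.0)
        assert rate == pytest.approx(2.1522e-4, rel=1e-3)

    def test_gamma_zero_se_flagged_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            shape, rate = gamma_from_moments(100.0, 0.0)
        assert np.isinf(shape) and np.isinf(rate)

    @pytest.mark.parametrize(
        "family,mean,se",
        [("beta", 0.27, 0.0172), ("beta", 0.91, 0.05), ("gamma", 116_160.0, 23_232.0)],
    )
    def test_sampled_moments_match_requested(self, family, mean, se):
        rng = np.random.default_rng(123)
        if family == "beta":
            a, b = beta_from_moments(mean, se)
            draws = rng.beta(a, b, size=1_000_000)
        else:
            shape, rate = gamma_from_moments(mean, se)
            draws = rng.gamma(shape, 1.0 / rate, size=1_000_000)
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.std() == pytest.approx(se, rel=0.01)
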