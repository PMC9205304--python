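"""Threshold calibration: error rates, grid optima, Bayes posteriors, bands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endosex as es
from endosex.exceptions import (
    BandCollapseError,
    NoThresholdError,
    SplineFitError,
    UndefinedProbabilityError,
)
from endosex.thresholds import error_rate_curves, threshold_grid

from conftest import brute_force_grid_threshold

values = st.lists(
    st.floats(min_value=0.5, max_value=500.0, allow_nan=False),
    min_size=2, max_size=30,
)


class TestErrorRates:
    def test_full_separation_zero_errors(self):
        er = es.classification_error_rates([1, 2], [10, 20], 5.0)
        assert (er.err_female, er.err_male) == (0.0, 0.0)

    def test_hand_enumerated_overlap(self, toy_overlapping):
        f, m = toy_overlapping
        er = es.classification_error_rates(f, m, 22.0)
        # females above 22: {30}; males below 22: {15}
        assert er.err_female == pytest.approx(1 / 3)
        assert er.err_male == pytest.approx(1 / 3)

    def test_threshold_below_everything(self):
        er = es.classification_error_rates([10, 20], [30, 40], 5.0)
        assert (er.err_female, er.err_male) == (1.0, 0.0)

    def test_value_at_threshold_counts_female(self):
        # strict inequalities: a male exactly at the threshold is not an error
        er = es.classification_error_rates([5.0], [10.0], 10.0)
        assert er.err_male == 0.0
        assert es.assign_sex_two_way(10.0, 10.0) == "F"

    def test_empty_sex_rejected(self):
        with pytest.raises(ValueError, match="F"):
            es.classification_error_rates([], [1.0], 0.5)

    @given(f=values, m=values, t=st.floats(min_value=0, max_value=600))
    @settings(max_examples=50, deadline=None)
    def test_reflection_swaps_error_rates(self, f, m, t):
        a = es.classification_error_rates(f, m, t)
        b = es.classification_error_rates([-v for v in m], [-v for v in f], -t)
        assert a.err_female == pytest.approx(b.err_male)
        assert a.err_male == pytest.approx(b.err_female)


class TestGridThresholds:
    def test_tm_separated_smallest_tiebreak(self):
        est = es.min_total_error_threshold([1, 2, 3], [10, 11, 12])
        assert est.value == pytest.approx(3.0)
        assert est.error_rates.total == 0.0

    def test_te_overlapping_toy(self, toy_overlapping):
        f, m = toy_overlapping
        est = es.equal_error_threshold(f, m)
        assert est.value == pytest.approx(20.0)
        assert est.error_rates.err_female == pytest.approx(1 / 3)
        assert est.error_rates.err_male == pytest.approx(1 / 3)

    def test_te_separated(self):
        est = es.equal_error_threshold([1, 2, 3], [10, 11, 12])
        assert est.value == pytest.approx(3.0)
        assert est.error_rates.total == 0.0

    def test_identical_lists_flagged_degenerate(self):
        vals = [5.0, 5.0, 5.0]
        est = es.equal_error_threshold(vals, vals)
        assert est.degenerate

    def test_identical_distributions_total_error_one(self):
        # off-grid continuous values: strict inequalities leave no ties
        rng = np.random.default_rng(0)
        v = rng.lognormal(3.0, 0.5, 40)
        grid = threshold_grid(np.concatenate([v, v]))
        ef, em = error_rate_curves(v, v, grid)
        on_data = np.isin(grid, v)
        assert np.allclose((ef + em)[~on_data], 1.0)

    def test_midpoint_tie_rule(self):
        # zero-error run spans [3.0, 10.0); midpoint rule picks its centre
        est = es.min_total_error_threshold([1, 2, 3], [10, 11, 12], tie="midpoint")
        assert 3.0 < est.value < 10.0

    @pytest.mark.parametrize("fit,objective", [
        (es.min_total_error_threshold, lambda ef, em: ef + em),
        (es.equal_error_threshold, lambda ef, em: abs(ef - em)),
    ])
    def test_matches_brute_force_oracle(self, fit, objective):
        rng = np.random.default_rng(42)
        for _ in range(25):
            f = rng.uniform(0, 60, rng.integers(2, 40))
            m = rng.uniform(10, 90, rng.integers(2, 40))
            expected_t, expected_rates = brute_force_grid_threshold(
                f.tolist(), m.tolist(), 0.1, objective
            )
            est = fit(f, m)
            assert est.value == pytest.approx(expected_t)
            assert est.error_rates.err_female == pytest.approx(expected_rates[0])
            assert est.error_rates.err_male == pytest.approx(expected_rates[1])

    @given(f=values, m=values)
    @settings(max_examples=50, deadline=None)
    def test_monotone_error_curves(self, f, m):
        grid = threshold_grid(np.concatenate([f, m]))
        ef, em = error_rate_curves(np.array(f), np.array(m), grid)
        assert np.all(np.diff(ef) <= 0)
        assert np.all(np.diff(em) >= 0)
        assert np.all((ef >= 0) & (ef <= 1) & (em >= 0) & (em <= 1))


class TestPosteriors:
    def test_identical_lists_give_half(self):
        v = [10.0, 20.0, 30.0]
        assert es.posterior_prob_female_below(v, v, 15.0) == pytest.approx(0.5)
        assert es.posterior_prob_male_above(v, v, 15.0) == pytest.approx(0.5)

    def test_hand_computed_values(self):
        assert es.posterior_prob_female_below([10, 20], [20, 30], 15.0) == 1.0
        assert es.posterior_prob_female_below(
            [10, 20, 30, 40], [25, 35, 45, 55], 30.0
        ) == pytest.approx(2 / 3)
        assert es.posterior_prob_male_above([10, 20], [20, 30], 25.0) == 1.0

    def test_empty_conditioning_event_raises(self):
        with pytest.raises(UndefinedProbabilityError):
            es.posterior_prob_female_below([10, 20], [30, 40], 5.0)

    @given(f=values, m=values, x0=st.floats(min_value=1, max_value=499))
    @settings(max_examples=50, deadline=None)
    def test_reflection_identity(self, f, m, x0):
        """male-above on (F, M) equals female-below on (-M, -F) at -x0."""
        try:
            a = es.posterior_prob_male_above(f, m, x0)
        except UndefinedProbabilityError:
            with pytest.raises(UndefinedProbabilityError):
                es.posterior_prob_female_below([-v for v in m], [-v for v in f], -x0)
            return
        b = es.posterior_prob_female_below([-v for v in m], [-v for v in f], -x0)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0


class TestProbabilityCurve:
    def test_gap_region_certainty(self, toy_separated):
        f, m = toy_separated
        curve = es.probability_curve(f, m)
        in_gap = (curve.grid > max(f)) & (curve.grid < min(m))
        assert np.allclose(curve.p_female_below[in_gap], 1.0)
        assert np.allclose(curve.p_male_above[in_gap], 1.0)

    def test_identical_distributions_pinned_at_half(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(3, 0.4, 30)
        curve = es.probability_curve(v, v)
        defined = np.isfinite(curve.p_female_below)
        assert np.allclose(curve.p_female_below[defined], 0.5)

    def test_endpoint_value(self):
        # at x0 = pooled max, p_female_below from per-sex shares strictly below
        f, m = [1.0, 2.0, 5.9], [3.0, 4.0, 6.0]
        curve = es.probability_curve(f, m)
        pf, pm = 3 / 3, 2 / 3  # f strictly below 6: all 3; m: 2 of 3
        assert curve.grid[-1] == pytest.approx(6.0)
        assert curve.p_female_below[-1] == pytest.approx(pf / (pf + pm))

    def test_undefined_points_flagged_not_imputed(self, toy_separated):
        f, m = toy_separated
        curve = es.probability_curve(f, m)
        assert np.isnan(curve.p_female_below[0])  # nothing strictly below min
        assert np.isnan(curve.p_male_above[-1])   # nothing strictly above max

    def test_grid_constant_step(self, toy_separated):
        curve = es.probability_curve(*toy_separated)
        steps = np.diff(curve.grid)
        assert np.allclose(steps, 0.1)

    def test_too_few_points_raises(self):
        with pytest.raises(SplineFitError):
            es.probability_curve([1.0, 1.05], [1.1, 1.15])


class TestLikelihoodThresholdsAndBand:
    def test_separated_threshold_in_gap(self, toy_separated):
        f, m = toy_separated
        curve = es.probability_curve(f, m)
        t_pf = es.likelihood_threshold(curve, 0.9, "F")
        t_pm = es.likelihood_threshold(curve, 0.9, "M")
        # one grid step of slack around the inter-class gap (5, 10)
        assert max(f) - 0.1 <= t_pf.value <= min(m) + 0.1
        assert max(f) - 0.1 <= t_pm.value <= min(m) + 0.1

    def test_identical_distributions_no_threshold(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(3, 0.4, 40)
        curve = es.probability_curve(v, v)
        with pytest.raises(NoThresholdError):
            es.likelihood_threshold(curve, 0.9, "F")

    def test_level_must_exceed_half(self, toy_separated):
        curve = es.probability_curve(*toy_separated)
        with pytest.raises(ValueError):
            es.likelihood_threshold(curve, 0.4, "F")

    def test_assign_sex_three_way(self):
        assert es.assign_sex(1.0, 3.0, 9.0) == "F"
        assert es.assign_sex(3.0, 3.0, 9.0) == "unknown"  # boundary -> unknown
        assert es.assign_sex(5.0, 3.0, 9.0) == "unknown"
        assert es.assign_sex(12.0, 3.0, 9.0) == "M"

    def test_inverted_band_signals_collapse(self):
        with pytest.raises(BandCollapseError):
            es.assign_sex(5.0, 9.0, 3.0)
        with pytest.raises(BandCollapseError):
            es.exclusion_rates([1, 2], [10, 11], 9.0, 3.0)

    def test_exclusion_rates(self, toy_separated):
        f, m = toy_separated
        assert es.exclusion_rates(f, m, 7.0, 8.0) == (0.0, 0.0)
        assert es.exclusion_rates(f, m, 0.5, 100.0) == (1.0, 1.0)
        # 6-point toy: one female and one male inside the band [4.5, 7]
        assert es.exclusion_rates(
            [1, 2, 6], [5, 10, 11], 4.5, 7.0
        ) == (pytest.approx(1 / 3), pytest.approx(1 / 3))
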