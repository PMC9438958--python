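import numpy as np
import pytest

import survdisc as sd
from survdisc.exceptions import DataValidationError, ImproperCurveError


def make_curves(grid, rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids if ids is not None else np.arange(rows.shape[0])
    return sd.SurvivalCurveMatrix(sd.TimeGrid(grid), rows, ids)


class TestProbAtTime:
    def test_before_grid_all_tied_at_minus_one(self, small_curves):
        rv = sd.prob_at_time(small_curves, 0.0)
        assert (rv.risk == -1.0).all()

    def test_orientation_lower_survival_higher_risk(self):
        c = make_curves([5.0], [[0.4], [0.9]])
        rv = sd.prob_at_time(c, 5.0)
        assert rv.risk[0] > rv.risk[1]

    def test_label_records_time(self, small_curves):
        assert "15" in sd.prob_at_time(small_curves, 15.0).label

    def test_negative_time_rejected(self, small_curves):
        with pytest.raises(DataValidationError):
            sd.prob_at_time(small_curves, -1.0)

    def test_ph_curves_recover_eta_ranking(self, ph_cohort):
        cohort, curves = ph_cohort
        t_mid = float(np.median(curves.grid.times))
        rv = sd.prob_at_time(curves, t_mid)
        assert (np.argsort(rv.risk) == np.argsort(cohort.eta)).all()


class TestExpectedMortality:
    def test_flat_one_curve_has_zero_hazard(self):
        c = make_curves([1.0, 2.0, 3.0], [[1.0, 1.0, 1.0]])
        assert sd.expected_mortality(c).risk[0] == 0.0

    def test_hand_computed_sum_of_logs(self):
        c = make_curves([1.0, 2.0, 3.0], [[1.0, 0.5, 0.25]])
        assert sd.expected_mortality(c).risk[0] == pytest.approx(np.log(2) + np.log(4))

    def test_pointwise_dominance_gives_strictly_larger_phi(self):
        c = make_curves([1.0, 2.0], [[1.0, 0.9], [1.0, 0.5]])
        phi = sd.expected_mortality(c).risk
        assert phi[1] > phi[0]

    def test_zero_survival_gives_posinf(self):
        c = make_curves([1.0, 2.0], [[0.5, 0.0]])
        assert np.isposinf(sd.expected_mortality(c).risk[0])

    def test_two_infinite_subjects_warn(self):
        c = make_curves([1.0], [[0.0], [0.0]])
        with pytest.warns(UserWarning, match="tie"):
            sd.expected_mortality(c)

    def test_label(self, small_curves):
        assert sd.expected_mortality(small_curves).label == "ExpMort"

    def test_grid_relabelling_preserves_ranking(self, ph_cohort):
        _, curves = ph_cohort
        phi1 = sd.expected_mortality(curves).risk
        stretched = sd.SurvivalCurveMatrix(
            sd.TimeGrid(curves.grid.times**2), curves.probabilities, curves.subject_ids
        )
        phi2 = sd.expected_mortality(stretched).risk
        assert (np.argsort(phi1) == np.argsort(phi2)).all()


class TestDropToZero:
    def test_appends_zero_point_at_offset(self):
        c = make_curves([100.0, 104.0], [[0.9, 0.81]])
        out = sd.drop_to_zero(c, sd.ImproperPolicy("drop", drop_offset=1.0))
        assert out.grid.times[-1] == 105.0
        assert out.probabilities[0, -1] == 0.0
        # pre-existing points untouched
        assert (out.probabilities[0, :-1] == c.probabilities[0]).all()

    def test_default_offset_is_smallest_grid_spacing(self):
        c = make_curves([1.0, 3.0, 4.0], [[0.9, 0.8, 0.7]])
        out = sd.drop_to_zero(c)
        assert out.grid.times[-1] == 5.0  # min spacing 1

    def test_proper_row_distribution_unchanged(self):
        c = make_curves([1.0, 2.0], [[0.5, 0.0]])
        naive = sd.curve_summary(c, sd.SummaryStatistic("mean"), sd.ImproperPolicy("naive"))
        dropped = sd.curve_summary(c, sd.SummaryStatistic("mean"), sd.ImproperPolicy("drop"))
        assert naive.risk[0] == dropped.risk[0]

    def test_remaining_mass_placed_at_appended_time(self):
        c = make_curves([104.0], [[0.81]])
        out = sd.drop_to_zero(c, sd.ImproperPolicy("drop", drop_offset=1.0))
        mass_at_end = out.probabilities[0, -2] - out.probabilities[0, -1]
        assert mass_at_end == pytest.approx(0.81)


class TestLinearExtrapolate:
    def test_zero_crossing_arithmetic(self):
        # line through (0,1) and (104, 0.81) hits 0 at 104/0.19
        c = make_curves([104.0], [[0.81]])
        out = sd.linear_extrapolate(c)
        assert out.grid.times[-1] == pytest.approx(104 / 0.19)
        assert out.probabilities[0, -1] == 0.0

    def test_half_crossing_on_the_line(self):
        c = make_curves([104.0], [[0.81]])
        out = sd.linear_extrapolate(c)
        t_half = 0.5 * 104 / 0.19  # solve 1 - (0.19/104) t = 0.5
        i = np.searchsorted(out.grid.times, t_half)
        # the discretized curve brackets 0.5 around the analytic crossing
        assert out.probabilities[0, i] <= 0.5 <= out.probabilities[0, max(i - 1, 0)]

    def test_proper_rows_unchanged(self):
        c = make_curves([1.0, 2.0], [[0.5, 0.0]])
        out = sd.linear_extrapolate(c)
        assert (out.probabilities == c.probabilities).all()

    def test_flat_row_rejected(self):
        c = make_curves([1.0, 2.0], [[1.0, 1.0]])
        with pytest.raises(ImproperCurveError, match="flat"):
            sd.linear_extrapolate(c)

    def test_output_proper_and_valid_with_mixed_rows(self):
        c = make_curves([1.0, 2.0, 3.0], [[0.9, 0.8, 0.7], [0.6, 0.3, 0.0], [0.5, 0.4, 0.35]])
        out = sd.validate_curves(sd.linear_extrapolate(c))
        assert (out.probabilities[:, -1] == 0.0).all()
        assert (out.probabilities[:, :3] == c.probabilities).all()


class TestCurveSummary:
    def test_proper_two_point_mean(self):
        c = make_curves([1.0, 2.0], [[0.5, 0.0]])
        rv = sd.curve_summary(c, sd.SummaryStatistic("mean"))
        assert rv.risk[0] == -1.5  # mean = 1*0.5 + 2*0.5

    def test_naive_mean_is_unnormalised_truncated_sum(self):
        c = make_curves([1.0, 2.0], [[0.8, 0.6]])
        rv = sd.curve_summary(c, sd.SummaryStatistic("mean"), sd.ImproperPolicy("naive"))
        assert rv.risk[0] == pytest.approx(-0.6)  # only 40% of the mass is in window

    def test_drop_mean_places_plateau_mass_at_end(self):
        c = make_curves([1.0, 2.0], [[0.8, 0.6]])
        rv = sd.curve_summary(
            c, sd.SummaryStatistic("mean"), sd.ImproperPolicy("drop", drop_offset=1.0)
        )
        assert rv.risk[0] == pytest.approx(-(0.6 + 3 * 0.6))

    def test_median_first_time_below_half(self):
        c = make_curves([1.0, 2.0], [[0.6, 0.4]])
        rv = sd.curve_summary(c, sd.SummaryStatistic("median"))
        assert rv.risk[0] == -2.0

    def test_naive_median_undefined_on_improper_row(self):
        c = make_curves([1.0, 2.0], [[0.9, 0.8]])
        with pytest.raises(ImproperCurveError, match="median undefined"):
            sd.curve_summary(c, sd.SummaryStatistic("median"), sd.ImproperPolicy("naive"))

    def test_drop_median_defined_on_improper_row(self):
        c = make_curves([1.0, 2.0], [[0.9, 0.8]])
        rv = sd.curve_summary(
            c, sd.SummaryStatistic("median"), sd.ImproperPolicy("drop", drop_offset=1.0)
        )
        assert rv.risk[0] == -3.0

    def test_label_names_stat_and_policy(self):
        c = make_curves([1.0, 2.0], [[0.5, 0.0]])
        rv = sd.curve_summary(c, sd.SummaryStatistic("mean"), sd.ImproperPolicy("drop"))
        assert "mean" in rv.label and "drop" in rv.label

    def test_policies_agree_on_proper_rows(self, ph_cohort):
        _, curves = ph_cohort
        # force rows proper by dropping survival to 0 at the final grid point
        probs = curves.probabilities.copy()
        probs[:, -1] = 0.0
        proper = sd.SurvivalCurveMatrix(curves.grid, probs, curves.subject_ids)
        means = {
            mode: sd.curve_summary(
                proper, sd.SummaryStatistic("mean"), sd.ImproperPolicy(mode)
            ).risk
            for mode in ("naive", "drop", "linear")
        }
        np.testing.assert_array_equal(means["naive"], means["drop"])
        np.testing.assert_array_equal(means["naive"], means["linear"])


class TestRankingProperties:
    def test_proper_curves_mean_and_expmort_recover_eta(self, ph_cohort):
        cohort, curves = ph_cohort
        dropped = sd.drop_to_zero(curves)
        order_eta = np.argsort(cohort.eta)
        mean_rank = np.argsort(
            sd.curve_summary(dropped, sd.SummaryStatistic("mean")).risk
        )
        mort_rank = np.argsort(sd.expected_mortality(curves).risk)
        assert (mean_rank == order_eta).all()
        assert (mort_rank == order_eta).all()

    def test_naive_mean_reverses_on_heavily_truncated_curves(self, ph_cohort):
        cohort, curves = ph_cohort
        t10 = float(np.quantile(cohort.outcomes.time, 0.10))
        trunc = sd.truncate_curves(curves, t10)
        c_naive = sd.harrell_c(
            cohort.outcomes,
            sd.curve_summary(trunc, sd.SummaryStatistic("mean"), sd.ImproperPolicy("naive")),
        ).value
        c_drop = sd.harrell_c(
            cohort.outcomes,
            sd.curve_summary(trunc, sd.SummaryStatistic("mean"), sd.ImproperPolicy("drop")),
        ).value
        assert c_naive < 0.5 < c_drop
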