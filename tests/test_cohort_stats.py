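import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qcart import datasets
from qcart.cohort_stats import (
    SpecimenRecord,
    build_difference_table,
    build_relaxation_table,
    fit_line,
    mri_vs_od_regression,
    od_time_regressions,
    percent_difference,
    relaxation_table_to_records,
)
from qcart.pipeline import published_difference_table, published_od_records

positive = st.floats(1e-3, 1e6)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (106.6, 54.6, 64.5),   # week-5 T2
            (2.98, 0.26, 167.9),   # week-10 optical density
            (137.9, 90.8, 41.2),   # week-3 spin-lock T1rho
        ],
    )
    def test_published_cells(self, a, b, expected):
        assert round(percent_difference(a, b), 1) == expected

    @given(x=positive)
    def test_identity_gives_zero(self, x):
        assert percent_difference(x, x) == 0.0

    @given(a=positive, b=positive)
    def test_antisymmetry(self, a, b):
        assert percent_difference(a, b) == pytest.approx(-percent_difference(b, a))

    @given(a=positive, b=positive)
    def test_bounded_and_ratio_form(self, a, b):
        d = percent_difference(a, b)
        assert -200.0 < d < 200.0
        r = a / b
        assert d == pytest.approx(200.0 * (r - 1.0) / (r + 1.0), rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


class TestRelaxationTable:
    def test_cells_match_input(self):
        rec = SpecimenRecord(week=5, lesion_class="LARGE",
                             stats={("T1RHO", "viable"): (88.0, 3.9),
                                    ("T1RHO", "necrotic"): (205.3, 18.1)})
        table = build_relaxation_table([rec])
        viable = table[(table.roi == "viable")].iloc[0]
        assert (viable["mean"], viable["sd"]) == (88.0, 3.9)

    def test_empty_record_list(self):
        assert len(build_relaxation_table([])) == 0

    def test_round_trip_identity(self):
        recs = [
            SpecimenRecord(week=w, lesion_class=datasets.lesion_class(w),
                           stats={(p, r): ms for r, by_p in datasets.RELAXATION_STATS[w].items()
                                  for p, ms in by_p.items()})
            for w in datasets.COHORT_WEEKS
        ]
        table = build_relaxation_table(recs)
        table2 = build_relaxation_table(relaxation_table_to_records(table))
        pd.testing.assert_frame_equal(
            table.sort_values(["week", "parameter", "roi"]).reset_index(drop=True),
            table2.sort_values(["week", "parameter", "roi"]).reset_index(drop=True),
        )

    def test_duplicate_cells_raise(self):
        rec = SpecimenRecord(week=5, lesion_class="LARGE",
                             stats={("T2", "viable"): (54.6, 4.4)})
        with pytest.raises(ValueError, match="duplicate"):
            build_relaxation_table([rec, rec])


class TestDifferenceTable:
    def test_published_cells(self):
        table = published_difference_table()
        assert round(table.loc[9, "T2"], 1) == 78.4
        assert round(table.loc[4, "RAFF"], 1) == 22.5
        assert round(table.loc[5, "T1RHO"], 1) == 80.0

    def test_week3_t2_cell_is_null(self):
        table = published_difference_table()
        assert np.isnan(table.loc[3, "T2"])

    def test_reproduces_printed_table_within_input_rounding(self):
        """Each printed difference cell is matched within the uncertainty
        implied by the rounding of its printed inputs (at least 0.1 pp)."""
        table = published_difference_table()
        for week, by_param in datasets.PRINTED_RELAXATION_DIFFERENCES.items():
            for param, printed in by_param.items():
                v, _ = datasets.RELAXATION_STATS[week]["viable"][param]
                n, _ = datasets.RELAXATION_STATS[week]["necrotic"][param]
                h = 0.5 * 10.0 ** -datasets.PRINTED_DECIMALS[param]
                bound = 400.0 * (v + n) / (v + n) ** 2 * h  # |dd/dv| + |dd/dn| times h
                tol = max(0.1, bound)
                assert table.loc[week, param] == pytest.approx(printed, abs=tol + 1e-9)


class TestFitLine:
    def test_exact_line(self):
        res = fit_line([0, 1, 2, 3], [1, 3, 5, 7])
        assert (res.slope, res.intercept, res.r_squared) == (2.0, 1.0, 1.0)

    def test_viable_od_regression_value(self):
        weeks = [3, 4, 5, 9, 10]
        viable = [datasets.OD_STATS[w]["viable"][0] for w in weeks]
        assert round(fit_line(weeks, viable).r_squared, 3) == 0.129

    def test_zero_covariance_gives_zero_slope(self):
        res = fit_line([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_raises_constant_y_is_flat(self):
        with pytest.raises(ValueError):
            fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        res = fit_line([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert (res.slope, res.r_squared) == (0.0, 0.0)

    @given(c=st.floats(0.1, 100.0))
    def test_scale_equivariance(self, c):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 3.0, 9.0, 11.0])
        base, scaled = fit_line(x, y), fit_line(x, c * y)
        assert scaled.slope == pytest.approx(c * base.slope)
        assert scaled.r_squared == pytest.approx(base.r_squared)


class TestODTimeRegressions:
    def test_week6_excluded_by_default(self):
        regs = od_time_regressions(published_od_records())
        assert regs["viable"].n_points == 5
        assert round(regs["viable"].r_squared, 3) == 0.129
        # both fits reported, neither forced onto the printed captions
        assert regs["necrotic"].r_squared == pytest.approx(0.993, abs=5e-4)
        assert regs["pct_diff"].r_squared == pytest.approx(0.989, abs=5e-4)

    def test_linear_decay_without_noise_has_unit_r2(self):
        recs = [
            SpecimenRecord(week=w, lesion_class=datasets.lesion_class(w),
                           od_stats={"viable": (3.0, 0.1),
                                     "necrotic": (3.0 - 0.25 * w, 0.1)})
            for w in (3, 5, 9)
        ]
        assert od_time_regressions(recs)["necrotic"].r_squared == pytest.approx(1.0)

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            od_time_regressions(published_od_records()[:2])


class TestMriVsOdRegression:
    @staticmethod
    def od_diffs():
        return {w: datasets.OD_STATS[w]["printed_difference"] for w in datasets.COHORT_WEEKS}

    def test_pooled_slope_on_printed_pairs(self):
        fit, points = mri_vs_od_regression(published_difference_table(), self.od_diffs())
        assert fit.n_points == 29 and len(points) == 29
        assert 0.20 <= fit.slope <= 0.23

    def test_identity_pairing(self):
        diff = pd.DataFrame({"T2": [10.0, 20.0, 30.0]}, index=[3, 5, 9])
        diff.index.name = "week"
        fit, _ = mri_vs_od_regression(diff, {3: 10.0, 5: 20.0, 9: 30.0})
        assert fit.slope == pytest.approx(1.0) and fit.r_squared == pytest.approx(1.0)

    def test_dropping_t1_changes_point_count_deterministically(self):
        table = published_difference_table()
        full, _ = mri_vs_od_regression(table, self.od_diffs())
        no_t1, pts = mri_vs_od_regression(table, self.od_diffs(),
                                          include_params=["T2", "T1RHO", "AD_T1RHO", "RAFF"])
        assert full.n_points - no_t1.n_points == 6
        assert no_t1.slope != full.slope
        rerun, _ = mri_vs_od_regression(table, self.od_diffs(),
                                        include_params=["T2", "T1RHO", "AD_T1RHO", "RAFF"])
        assert rerun.slope == no_t1.slope


def test_specimen_record_validation():
    with pytest.raises(ValueError):
        SpecimenRecord(week=0, lesion_class="LARGE")
    with pytest.raises(ValueError):
        SpecimenRecord(week=3, lesion_class="MEDIUM")
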