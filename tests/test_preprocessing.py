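"""Preprocessing: normalisation, cadence conversion, variants, pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamcast.errors import (
    DegenerateVariableError,
    InterpolationError,
    VariantError,
)
from gamcast.preprocessing import (
    aggregate_monthly_to_biannual,
    interpolate_biannual_to_monthly,
    make_variant,
    prune_correlated,
    spatial_interpolate,
    zscore_normalise,
)

MONTHS = pd.period_range("2018-01", "2018-12", freq="M")


def monthly_series(values, start="2018-01"):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(values, index=idx, dtype=float)


class TestZScore:
    def test_basic(self):
        np.testing.assert_allclose(
            zscore_normalise(pd.Series([1.0, 2.0, 3.0])), [-1, 0, 1]
        )

    def test_idempotent(self):
        x = pd.Series([3.0, 1.0, 4.0, 1.0, 5.0])
        once = zscore_normalise(x)
        pd.testing.assert_series_equal(zscore_normalise(once), once)

    def test_constant_raises(self):
        with pytest.raises(DegenerateVariableError):
            zscore_normalise(pd.Series([5.0, 5.0, 5.0]))

    @given(
        a=st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_shift_invariance(self, a, b):
        x = pd.Series([0.0, 1.0, 3.0, 7.0, 2.0])
        base = zscore_normalise(x)
        scaled = zscore_normalise(a * x + b)
        np.testing.assert_allclose(scaled, np.sign(a) * base, atol=1e-9)


class TestInterpolation:
    def test_midpoint_and_intermediate_months(self):
        s = pd.Series(
            {pd.Period("2018-01", "M"): 10.0, pd.Period("2018-07", "M"): 16.0}
        )
        out = interpolate_biannual_to_monthly(s, MONTHS)
        # line value₁ + (m−1)·(value₇−value₁)/6
        for month, expected in [("2018-02", 11), ("2018-03", 12), ("2018-04", 13),
                                ("2018-05", 14), ("2018-06", 15)]:
            assert out[pd.Period(month, "M")] == pytest.approx(expected)
        assert out[pd.Period("2018-01", "M")] == 10.0
        assert out[pd.Period("2018-07", "M")] == 16.0

    def test_constant_segment(self):
        s = pd.Series(
            {pd.Period("2018-01", "M"): 10.0, pd.Period("2018-07", "M"): 10.0}
        )
        out = interpolate_biannual_to_monthly(s, MONTHS)
        assert (out.loc["2018-01":"2018-07"] == 10.0).all()

    def test_no_extrapolation(self):
        s = pd.Series(
            {pd.Period("2018-01", "M"): 10.0, pd.Period("2018-07", "M"): 16.0}
        )
        out = interpolate_biannual_to_monthly(s, MONTHS)
        assert out.loc["2018-08":].isna().all()

    def test_single_observation_raises(self):
        s = pd.Series({pd.Period("2018-01", "M"): 10.0})
        with pytest.raises(InterpolationError):
            interpolate_biannual_to_monthly(s, MONTHS)


class TestAggregation:
    def test_constant_window(self):
        s = monthly_series([np.nan, 4, 4, 4, 4, 4, 4] + [np.nan] * 5)
        out = aggregate_monthly_to_biannual(s)
        assert out[pd.Period("2018-07", "M")] == pytest.approx(4.0)

    def test_mean_of_one_to_six(self):
        s = monthly_series([np.nan, 1, 2, 3, 4, 5, 6] + [np.nan] * 5)
        out = aggregate_monthly_to_biannual(s)
        assert out[pd.Period("2018-07", "M")] == pytest.approx(3.5)

    def test_missing_month_propagates(self):
        s = monthly_series([np.nan, 1, np.nan, 3, 4, 5, 6] + [np.nan] * 5)
        out = aggregate_monthly_to_biannual(s)
        assert np.isnan(out[pd.Period("2018-07", "M")])


class TestVariants:
    def test_three_month_sum_excludes_current_month(self):
        s = monthly_series([1, 2, 3, 4])
        out = make_variant(s, "3sum")
        assert out.iloc[3] == pytest.approx(6.0)  # 1+2+3, not 2+3+4
        assert out.iloc[:3].isna().all()

    def test_one_month_lag(self):
        s = monthly_series([1, 2, 3, 4])
        assert make_variant(s, "1lag").iloc[3] == 3.0

    def test_biannual_six_month_lag_shifts_one_period(self):
        idx = pd.PeriodIndex(["2018-01", "2018-07", "2019-01"], freq="M")
        s = pd.Series([10.0, 20.0, 30.0], index=idx)
        out = make_variant(s, "6lag", cadence="biannual")
        assert out.iloc[2] == 20.0

    def test_window_variant_invalid_on_biannual(self):
        idx = pd.PeriodIndex(["2018-01", "2018-07"], freq="M")
        s = pd.Series([1.0, 2.0], index=idx)
        with pytest.raises(VariantError):
            make_variant(s, "3sum", cadence="biannual")

    def test_variant_commutes_with_district_partition(self):
        rng = np.random.default_rng(4)
        frames = {
            d: monthly_series(rng.normal(size=12)) for d in range(3)
        }
        per_district = pd.concat(
            {d: make_variant(s, "3avg") for d, s in frames.items()}
        )
        joint = pd.concat(frames).groupby(level=0, group_keys=True).apply(
            lambda s: make_variant(s.droplevel(0), "3avg")
        )
        pd.testing.assert_series_equal(per_district, joint, check_names=False)


class TestPruning:
    def test_identical_columns_one_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out, dropped = prune_correlated(df, 0.9)
        assert len(out.columns) == 1 and len(dropped) == 1

    def test_negated_column_dropped_by_absolute_rule(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [-1.0, -2, -3, -4]})
        out, dropped = prune_correlated(df, 0.9)
        assert len(out.columns) == 1
        assert dropped[0][2] == pytest.approx(-1.0)

    def test_under_five_population_case(self):
        """A near-duplicate of total population (under-5 count) is pruned;
        the column with fewer missing values survives."""
        rng = np.random.default_rng(0)
        pop = rng.uniform(1e4, 5e5, 60)
        under5 = 0.18 * pop * rng.normal(1.0, 0.005, 60)
        df = pd.DataFrame({"population": pop, "under5": under5})
        df.loc[:4, "under5"] = np.nan
        out, dropped = prune_correlated(df, 0.9)
        assert list(out.columns) == ["population"]
        assert dropped[0][0] == "under5"

    def test_uncorrelated_untouched(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        out, dropped = prune_correlated(df, 0.9)
        assert dropped == [] and list(out.columns) == list("abc")


class TestSpatialInterpolation:
    ADJ = {0: [1, 2], 1: [0], 2: [0], 3: []}

    def test_neighbour_mean(self):
        v = pd.Series({0: np.nan, 1: 10.0, 2: 20.0, 3: 7.0})
        out = spatial_interpolate(v, self.ADJ)
        assert out[0] == pytest.approx(15.0)

    def test_national_mean_fallback(self):
        v = pd.Series({0: 10.0, 1: 14.0, 2: np.nan, 3: np.nan})
        adj = {2: [3], 3: [2]}
        out = spatial_interpolate(v, adj)
        assert out[2] == pytest.approx(12.0)
        assert out[3] == pytest.approx(12.0)

    def test_identity_when_complete(self):
        v = pd.Series({0: 1.0, 1: 2.0})
        pd.testing.assert_series_equal(spatial_interpolate(v, self.ADJ), v)

    def test_nothing_observed_raises(self):
        v = pd.Series({0: np.nan, 1: np.nan})
        with pytest.raises(InterpolationError):
            spatial_interpolate(v, self.ADJ)


class TestBuildTables:
    def test_round_trip_constant_series_exact(self):
        s = pd.Series(
            {pd.Period("2018-01", "M"): 8.0, pd.Period("2018-07", "M"): 8.0,
             pd.Period("2019-01", "M"): 8.0}
        )
        months = pd.period_range("2018-01", "2019-01", freq="M")
        monthly = interpolate_biannual_to_monthly(s, months)
        back = aggregate_monthly_to_biannual(monthly)
        assert back[pd.Period("2018-07", "M")] == pytest.approx(8.0)
        assert back[pd.Period("2019-01", "M")] == pytest.approx(8.0)

    def test_normalised_columns_standardised(self, analysis_tables):
        monthly, _, _ = analysis_tables
        for col in monthly.feature_columns:
            assert monthly.frame[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert monthly.frame[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_monthly_table_has_no_missing_values(self, analysis_tables):
        monthly, _, _ = analysis_tables
        assert not monthly.frame.isna().any().any()

    def test_biannual_table_keeps_only_complete_districts(self, analysis_tables):
        _, biannual, counts = analysis_tables
        per_district = biannual.frame.groupby("district_id")["gam"].count()
        assert (per_district == 9).all()
        assert counts["biannual_districts"] == 65

    def test_row_counts_monotone(self, analysis_tables):
        _, _, counts = analysis_tables
        assert counts["monthly_retained"] <= counts["potential_monthly"]
        assert counts["biannual_rows"] <= counts["potential_biannual"]
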