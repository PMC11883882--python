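"""Relationship analysis: levels, simple OLS, nature, multiple regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamcast.errors import DataSufficiencyError, DegenerateVariableError, GamcastError
from gamcast.relationships import (
    SignificanceLevel,
    build_relationship_table,
    classify_nature,
    model_variant_set,
    multiple_regression,
    newey_west_lags,
    simple_dummy_levels,
    simple_ols,
)
from gamcast.synthetic import apply_link


class TestSignificanceLevel:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.005, "very_high"),
            (0.01, "very_high"),
            (0.010001, "high"),
            (0.05, "high"),
            (0.2, "low"),
            (0.3, "low"),
            (0.31, "very_low"),
            (1.0, "very_low"),
            (0.0, "very_high"),
        ],
    )
    def test_boundaries(self, p, expected):
        assert SignificanceLevel.from_p(p).value == expected

    @given(st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, p):
        """Every p in [0,1] maps to exactly one level."""
        level = SignificanceLevel.from_p(p)
        assert level in SignificanceLevel

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SignificanceLevel.from_p(1.5)


class TestSimpleOls:
    def test_exact_line_recovers_slope_very_high(self):
        x = np.linspace(0, 1, 40)
        slope, p, level = simple_ols(2 * x + 1, x)
        assert slope == pytest.approx(2.0)
        assert p < 1e-10 and level is SignificanceLevel.VERY_HIGH

    def test_constant_regressor_raises(self):
        with pytest.raises(DegenerateVariableError):
            simple_ols(np.arange(5.0), np.ones(5))

    def test_too_few_pairs_raises(self):
        with pytest.raises(DataSufficiencyError):
            simple_ols(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_type_one_error_near_nominal(self):
        """Independent x: ~5% of replicates reach the 0.05 boundary."""
        rng = np.random.default_rng(123)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=500)
            y = rng.normal(size=500)
            _, _, level = simple_ols(y, x)
            hits += level.established
        rate = hits / reps
        assert 0.02 < rate < 0.09  # binomial 3σ band around 0.05


def _region_frame(rng, link, effect, loc, n_regions=6, n=120):
    frames = []
    for r in range(n_regions):
        x = rng.normal(0, 1, n)
        y = 14.5 + apply_link(x, link, effect, loc) + rng.normal(0, 1, n)
        frames.append(
            pd.DataFrame({"region_id": r, "gam": y, "cov__0lag": x})
        )
    return pd.concat(frames, ignore_index=True)


class TestClassifyNature:
    def test_majority_rule_exact_half_is_linear(self, monkeypatch):
        # 3 of 6 regions linear passes "at least 50%"
        import gamcast.relationships as rel

        outcomes = iter(["linear", "linear", "linear",
                         "nonlinear", "nonlinear", "nonlinear"])
        monkeypatch.setattr(
            rel, "containment_test", lambda lb, kb: next(outcomes)
        )
        rng = np.random.default_rng(0)
        frame = _region_frame(rng, "linear", 2.0, 0.0)
        nature, r_lin, r_tot = classify_nature(frame, "cov__0lag")
        assert (nature, r_lin, r_tot) == ("linear", 3, 6)

    def test_sparse_regions_excluded_from_denominator(self):
        rng = np.random.default_rng(1)
        frame = _region_frame(rng, "linear", 2.0, 0.0)
        tiny = pd.DataFrame(
            {"region_id": 99, "gam": [14.0, 15.0], "cov__0lag": [0.0, 1.0]}
        )
        frame = pd.concat([frame, tiny], ignore_index=True)
        _, _, r_tot = classify_nature(frame, "cov__0lag")
        assert r_tot == 6

    def test_all_regions_unusable_raises(self):
        frame = pd.DataFrame(
            {"region_id": [0] * 5, "gam": np.arange(5.0), "cov__0lag": np.ones(5)}
        )
        with pytest.raises(DataSufficiencyError):
            classify_nature(frame, "cov__0lag")

    def test_hinge_detected_nonlinear_single_seed(self):
        rng = np.random.default_rng(2)
        frame = _region_frame(rng, "hinge", 1.5, 0.25, n_regions=6, n=200)
        nature, _, _ = classify_nature(frame, "cov__0lag")
        assert nature == "nonlinear"

    def test_linear_detected_linear_single_seed(self):
        rng = np.random.default_rng(3)
        frame = _region_frame(rng, "linear", 1.5, 0.0, n_regions=6, n=200)
        nature, _, _ = classify_nature(frame, "cov__0lag")
        assert nature == "linear"


class TestModelVariantSets:
    COLUMNS = [
        "gam__6lag",
        "conflicts__0lag", "conflicts__1lag", "conflicts__3sum",
        "ndvi__0lag", "ndvi__1lag", "ndvi__3avg",
        "ipc__0lag", "ipc__6lag",
    ]

    def test_model_definitions(self):
        m1 = set(model_variant_set(self.COLUMNS, 1))
        assert m1 == {"gam__6lag", "conflicts__0lag", "ndvi__0lag", "ipc__0lag"}
        m2 = set(model_variant_set(self.COLUMNS, 2))
        assert m2 == {"gam__6lag", "conflicts__1lag", "ndvi__1lag", "ipc__6lag"}
        m3 = set(model_variant_set(self.COLUMNS, 3))
        assert m3 == {"gam__6lag", "conflicts__3sum", "ndvi__3avg", "ipc__6lag"}

    def test_at_most_one_variant_per_base(self):
        for mid in (1, 2, 3):
            chosen = model_variant_set(self.COLUMNS, mid)
            bases = [c.rsplit("__", 1)[0] for c in chosen]
            assert len(bases) == len(set(bases))


def _panel_monthly_frame(rng, n_districts=20, n_months=40, beta=None):
    months = pd.period_range("2018-01", periods=n_months, freq="M")
    rows = []
    for d in range(n_districts):
        x1 = rng.normal(0, 1, n_months)
        x2 = rng.normal(0, 1, n_months)
        noise = rng.normal(0, 1, n_months)
        y = 10 + (beta or 0.0) * x1 + noise
        for t, m in enumerate(months):
            rows.append(
                {"date": m, "district_id": d, "region_id": d % 4,
                 "gam": y[t], "x1__0lag": x1[t], "x2__0lag": x2[t],
                 "gam__6lag": 10 + rng.normal()}
            )
    return pd.DataFrame(rows)


class TestMultipleRegression:
    def test_duplicate_variant_precondition(self):
        rng = np.random.default_rng(0)
        frame = _panel_monthly_frame(rng)
        with pytest.raises(GamcastError, match="same base variable"):
            multiple_regression(
                frame, 1, variant_columns=["x1__0lag", "x1__0lag"]
            )

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(1)
        frame = _panel_monthly_frame(rng)
        frame["x2__0lag"] = 2.0 * frame["x1__0lag"]
        with pytest.raises(GamcastError, match="collinear"):
            multiple_regression(frame, 1)

    def test_zero_lag_hac_matches_white(self):
        """Newey-West with 0 lags on iid residuals ≈ White p-values."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        frame = _panel_monthly_frame(rng, beta=0.3)
        res = multiple_regression(frame, 1, nw_lags=0)
        cols = ["x1__0lag", "x2__0lag", "gam__6lag"]
        frame_s = frame.sort_values(["district_id", "date"])
        X = frame_s[cols].astype(float)
        md = pd.get_dummies(frame_s["date"].dt.month.astype("category"),
                            prefix="month", drop_first=True).astype(float)
        rd = pd.get_dummies(frame_s["region_id"].astype("category"),
                            prefix="region", drop_first=True).astype(float)
        X = sm.add_constant(
            pd.concat([X.reset_index(drop=True), md.reset_index(drop=True),
                       rd.reset_index(drop=True)], axis=1)
        )
        white = sm.OLS(frame_s["gam"].to_numpy(), X).fit(cov_type="HC1")
        for col in cols:
            assert res.pvalues[col] == pytest.approx(
                float(white.pvalues[col]), rel=1e-6
            )

    def test_signal_and_null_separated(self):
        rng = np.random.default_rng(3)
        frame = _panel_monthly_frame(rng, beta=0.5)
        res = multiple_regression(frame, 1)
        assert res.variant_levels["x1__0lag"][1].established
        assert res.variant_levels["x2__0lag"][0] > 0.01

    def test_group_f_tests_reported(self):
        rng = np.random.default_rng(4)
        frame = _panel_monthly_frame(rng, beta=0.2)
        res = multiple_regression(frame, 1)
        assert 0 <= res.month_group[0] <= 1
        assert 0 <= res.region_group[0] <= 1


class TestRelationshipTable:
    def test_selection_rule_simple_or_multiple(self, analysis_tables):
        monthly, _, _ = analysis_tables
        table = build_relationship_table(monthly.frame, compute_nature=False)
        df = table.to_frame()
        for base in {r.variable for r in table.rows}:
            sub = df[df["variable"] == base]
            established = (
                sub["simple_p"].le(0.05).any() or sub["multiple_p"].le(0.05).any()
            )
            assert (base in table.selected) == established

    def test_dummy_simple_levels_cover_all_categories(self, analysis_tables):
        monthly, _, _ = analysis_tables
        months = simple_dummy_levels(monthly.frame, "month")
        regions = simple_dummy_levels(monthly.frame, "region")
        assert len(months) == 12
        assert len(regions) == 18


def test_newey_west_plugin_rule():
    assert newey_west_lags(100) == 4
    assert newey_west_lags(3122) == int(np.floor(4 * (3122 / 100) ** (2 / 9)))
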