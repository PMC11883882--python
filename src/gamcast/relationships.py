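"""Three-step statistical relationship analysis.

Step 1 — simple OLS of GAM on each covariate variant, classifying the slope
p-value into four association levels (very_high: p ≤ 0.01; high: p ≤ 0.05;
low: p ≤ 0.3; very_low: p > 0.3).

Step 2 — linear/nonlinear nature per variant by the band-containment test of
:mod:`gamcast.bands`, run region by region; a variant is linear when at least
50% of usable regions yield containment.

Step 3 — multiple OLS with month and region dummies and Newey-West (HAC)
standard errors, in three models that never include two variants of the same
base variable (model 1: original 0lag variants; model 2: 1- or 6-month lags;
model 3: 6-month lags or 3-month windows), plus group F-tests for the month
and region dummies.

A base variable is *selected* for forecasting when any of its variants
reaches high/very_high in the simple regression or in any multiple model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from gamcast.bands import (
    Band,
    containment_test,
    ols_band,
    rule_of_thumb_bandwidth,
    trimmed_grid,
    uniform_band,
)
from gamcast.errors import (
    CoverageError,
    DataSufficiencyError,
    DegenerateVariableError,
    GamcastError,
)

logger = logging.getLogger(__name__)


class SignificanceLevel(str, Enum):
    """Four-level association classification from a p-value."""

    VERY_HIGH = "very_high"
    HIGH = "high"
    LOW = "low"
    VERY_LOW = "very_low"

    @classmethod
    def from_p(cls, p: float) -> "SignificanceLevel":
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0,1]: {p}")
        if p <= 0.01:
            return cls.VERY_HIGH
        if p <= 0.05:
            return cls.HIGH
        if p <= 0.3:
            return cls.LOW
        return cls.VERY_LOW

    @property
    def established(self) -> bool:
        """High or very high association."""
        return self in (SignificanceLevel.VERY_HIGH, SignificanceLevel.HIGH)


def simple_ols(y, x) -> tuple[float, float, SignificanceLevel]:
    """OLS of y on x with intercept; two-sided t-test p for the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DataSufficiencyError(f"simple OLS needs ≥3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateVariableError("simple OLS regressor is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue), SignificanceLevel.from_p(res.pvalue)


def newey_west_lags(n: int) -> int:
    """Standard plug-in truncation lag floor(4·(n/100)^(2/9))."""
    return int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


def classify_nature(
    monthly: pd.DataFrame,
    column: str,
    target: str = "gam",
    region_col: str = "region_id",
    n_grid: int = 100,
    trim: tuple[float, float] = (0.05, 0.95),
    bandwidth_multiplier: float = 1.0,
    simultaneous_ols: bool = True,
    min_region_n: int = 30,
) -> tuple[str, int, int]:
    """Linear/nonlinear nature of one covariate variant, by region.

    Runs the band-containment test within each region; regions with too few
    observations or degenerate covariates are excluded from the denominator
    (and logged).  Returns (nature, regions_linear, regions_total).
    """
    regions_linear = 0
    regions_total = 0
    for region, sub in monthly.groupby(region_col):
        x = sub[column].to_numpy(float)
        y = sub[target].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < min_region_n:
            logger.info("region %s skipped for %s: n=%d", region, column, x.size)
            continue
        try:
            h = bandwidth_multiplier * rule_of_thumb_bandwidth(x)
            grid = trimmed_grid(x, n_grid, trim)
            kb = uniform_band(x, y, h=h, grid=grid)
            lb = ols_band(x, y, grid, simultaneous=simultaneous_ols)
            verdict = containment_test(lb, kb)
        except (DegenerateVariableError, CoverageError) as exc:
            logger.info("region %s unusable for %s: %s", region, column, exc)
            continue
        regions_total += 1
        regions_linear += verdict == "linear"
    if regions_total == 0:
        raise DataSufficiencyError(
            f"nature of {column!r} undetermined: no region usable"
        )
    nature = "linear" if regions_linear / regions_total >= 0.5 else "nonlinear"
    return nature, regions_linear, regions_total


# ---------------------------------------------------------------------------
# multiple regression


def model_variant_set(columns: list[str], model_id: int) -> list[str]:
    """Variant columns entering each multiple-regression model.

    Model 1: the original (0lag) variants.  Model 2: a 1-month lag for
    monthly covariates, a 6-month lag otherwise.  Model 3: 6-month lags, or
    the 3-month sum/average for monthly covariates.  The 6-month lag of GAM
    enters every model.  At most one variant per base variable.
    """
    if model_id not in (1, 2, 3):
        raise ValueError(f"model_id must be 1, 2 or 3, got {model_id}")
    by_base: dict[str, dict[str, str]] = {}
    for col in columns:
        if "__" not in col:
            continue
        base, kind = col.rsplit("__", 1)
        by_base.setdefault(base, {})[kind] = col
    preference = {
        1: ("0lag",),
        2: ("1lag", "6lag"),
        3: ("3sum", "3avg", "6lag"),
    }[model_id]
    chosen: list[str] = []
    for base, kinds in by_base.items():
        if base == "gam":
            if "6lag" in kinds:
                chosen.append(kinds["6lag"])
            continue
        for kind in preference:
            if kind in kinds:
                chosen.append(kinds[kind])
                break
    return chosen


def _validate_variant_set(columns: list[str]) -> None:
    bases = [c.rsplit("__", 1)[0] for c in columns]
    dupes = {b for b in bases if bases.count(b) > 1}
    if dupes:
        raise GamcastError(
            f"two variants of the same base variable in one model: {sorted(dupes)}"
        )


@dataclass
class MultipleRegressionResult:
    model_id: int
    variant_levels: dict[str, tuple[float, SignificanceLevel]]
    month_group: tuple[float, SignificanceLevel]
    region_group: tuple[float, SignificanceLevel]
    nobs: int
    nw_lags: int
    params: pd.Series = field(repr=False, default=None)
    pvalues: pd.Series = field(repr=False, default=None)
    bse: pd.Series = field(repr=False, default=None)


def multiple_regression(
    monthly: pd.DataFrame,
    model_id: int,
    target: str = "gam",
    nw_lags: int | None = None,
    variant_columns: list[str] | None = None,
) -> MultipleRegressionResult:
    """One multiple-regression model with dummies and Newey-West errors.

    Month dummies (11, January reference) and region dummies (first region
    reference) always enter; per-coefficient p-values use the HAC covariance
    with truncation lag ``nw_lags`` (plug-in default); month and region
    groups are tested jointly with F-tests under the same covariance.
    """
    cols = variant_columns or model_variant_set(list(monthly.columns), model_id)
    _validate_variant_set(cols)
    if not cols:
        raise DataSufficiencyError(f"model {model_id}: no variant columns available")

    # district-major ordering so HAC lags run along each district's time axis
    frame = monthly.dropna(subset=cols + [target]).sort_values(
        ["district_id", "date"]
    )
    y = frame[target].to_numpy(float)
    X = frame[cols].astype(float).copy()

    month_dummies = pd.get_dummies(
        frame["date"].dt.month.astype("category"), prefix="month", drop_first=True
    ).astype(float)
    region_dummies = pd.get_dummies(
        frame["region_id"].astype("category"), prefix="region", drop_first=True
    ).astype(float)
    X = pd.concat(
        [X.reset_index(drop=True), month_dummies.reset_index(drop=True),
         region_dummies.reset_index(drop=True)],
        axis=1,
    )
    X = sm.add_constant(X)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name aliased columns by inspecting the QR diagonal
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[i] for i in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise GamcastError(f"collinear design; aliased columns: {aliased}")

    lags = newey_west_lags(len(frame)) if nw_lags is None else nw_lags
    # panel form of the Newey-West estimator: the Bartlett kernel is applied
    # within each district's time series, never across district boundaries
    fit = sm.OLS(y, X).fit(
        cov_type="hac-panel",
        cov_kwds={
            "groups": frame["district_id"].reset_index(drop=True),
            "maxlags": lags,
        },
    )

    variant_levels = {
        c: (float(fit.pvalues[c]), SignificanceLevel.from_p(float(fit.pvalues[c])))
        for c in cols
    }

    def group_test(prefix: str) -> tuple[float, SignificanceLevel]:
        names = [c for c in X.columns if c.startswith(prefix)]
        restriction = np.zeros((len(names), X.shape[1]))
        for i, name in enumerate(names):
            restriction[i, X.columns.get_loc(name)] = 1.0
        p = float(fit.f_test(restriction).pvalue)
        return p, SignificanceLevel.from_p(p)

    return MultipleRegressionResult(
        model_id=model_id,
        variant_levels=variant_levels,
        month_group=group_test("month_"),
        region_group=group_test("region_"),
        nobs=len(frame),
        nw_lags=lags,
        params=fit.params,
        pvalues=fit.pvalues,
        bse=fit.bse,
    )


def simple_dummy_levels(
    monthly: pd.DataFrame, kind: str = "month", target: str = "gam"
) -> dict[str, SignificanceLevel]:
    """Association level of each month/region dummy regressed on GAM alone.

    Mirrors the per-variable simple-regression step for the dummy rows of
    the summary table: one 0/1 indicator per calendar month or region.
    """
    if kind == "month":
        labels = monthly["date"].dt.month
    elif kind == "region":
        labels = monthly["region_id"]
    else:
        raise ValueError(f"kind must be 'month' or 'region', got {kind!r}")
    out: dict[str, SignificanceLevel] = {}
    for value in sorted(labels.unique()):
        indicator = (labels == value).astype(float)
        try:
            _, _, lvl = simple_ols(monthly[target], indicator)
        except DegenerateVariableError:
            continue
        out[f"{kind}_{value}"] = lvl
    return out


# ---------------------------------------------------------------------------
# the full table


@dataclass
class RelationshipRow:
    variable: str
    variant: str
    simple_p: float
    simple_level: SignificanceLevel
    nature: str | None
    regions_linear: int | None
    regions_total: int | None
    multiple_p: float | None
    multiple_level: SignificanceLevel | None


@dataclass
class RelationshipTable:
    """Per-variant association summary plus the selected-variable list."""

    rows: list[RelationshipRow]
    month_group: dict[int, tuple[float, SignificanceLevel]]
    region_group: dict[int, tuple[float, SignificanceLevel]]
    selected: list[str]
    model_results: dict[int, MultipleRegressionResult] = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "variable": r.variable,
                    "variant": r.variant,
                    "simple_p": r.simple_p,
                    "simple_level": r.simple_level.value,
                    "nature": r.nature,
                    "regions_linear": r.regions_linear,
                    "regions_total": r.regions_total,
                    "multiple_p": r.multiple_p,
                    "multiple_level": (
                        r.multiple_level.value if r.multiple_level else None
                    ),
                }
            )
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_relationship_table(
    monthly: pd.DataFrame,
    compute_nature: bool = True,
    nature_kwargs: dict | None = None,
    nw_lags: int | None = None,
) -> RelationshipTable:
    """Run all three steps and assemble the per-variant summary.

    ``compute_nature=False`` skips the (slower) band-containment step, which
    is not needed when only variable selection is of interest.  When a
    variant appears in more than one multiple model, the summary reports the
    level from the lowest-numbered model containing it; the full per-model
    results stay available in ``model_results``.
    """
    variant_cols = [c for c in monthly.columns if "__" in c]
    if not variant_cols:
        raise DataSufficiencyError("monthly table contains no variant columns")

    model_results: dict[int, MultipleRegressionResult] = {}
    for mid in (1, 2, 3):
        cols = model_variant_set(variant_cols, mid)
        if cols:
            model_results[mid] = multiple_regression(
                monthly, mid, nw_lags=nw_lags, variant_columns=cols
            )

    multiple_of: dict[str, tuple[float, SignificanceLevel]] = {}
    for mid in sorted(model_results):
        for col, (p, lvl) in model_results[mid].variant_levels.items():
            multiple_of.setdefault(col, (p, lvl))

    rows: list[RelationshipRow] = []
    established: dict[str, bool] = {}
    for col in variant_cols:
        base, kind = col.rsplit("__", 1)
        slope, p, lvl = simple_ols(monthly["gam"], monthly[col])
        if compute_nature:
            nature, r_lin, r_tot = classify_nature(
                monthly, col, **(nature_kwargs or {})
            )
        else:
            nature = r_lin = r_tot = None
        mp = multiple_of.get(col)
        rows.append(
            RelationshipRow(
                variable=base,
                variant=kind,
                simple_p=p,
                simple_level=lvl,
                nature=nature,
                regions_linear=r_lin,
                regions_total=r_tot,
                multiple_p=mp[0] if mp else None,
                multiple_level=mp[1] if mp else None,
            )
        )
        hit = lvl.established or (mp is not None and mp[1].established)
        established[base] = established.get(base, False) or hit

    # the dummy-group rows of the summary (per-model)
    month_group = {m: r.month_group for m, r in model_results.items()}
    region_group = {m: r.region_group for m, r in model_results.items()}

    selected = sorted(b for b, hit in established.items() if hit)
    return RelationshipTable(rows, month_group, region_group, selected, model_results)
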