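"""Panel preprocessing: normalisation, cadence conversion, derived variants.

Turns a long-format district×month panel into the two analysis-ready wide
tables: a *monthly* table (biannual series linearly interpolated upward) for
the statistical relationship analysis, and a *biannual* table (monthly series
averaged downward) for forecasting.  Column names follow the scheme
``base__variant`` (e.g. ``rainfall__3sum``); the GAM target column is ``gam``.

Conventions (configurable where noted):

* z-scores use the sample SD (denominator n−1);
* "preceding 3 months" windows cover months t−1..t−3, excluding the current
  month;
* the 6-month aggregation window for a biannual point is the 6 calendar
  months ending at (and including) the observation month (Feb–Jul for a July
  survey, Aug–Jan for a January survey);
* correlation pruning removes, from any pair with |r| above the threshold,
  the variable with more missing values (tie → the later one in column
  order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gamcast.errors import (
    DataSufficiencyError,
    DegenerateVariableError,
    InterpolationError,
    VariantError,
)
from gamcast.synthetic import BIANNUAL_MONTHS, PanelDataset

logger = logging.getLogger(__name__)

MONTHLY_VARIANTS = ("0lag", "1lag", "3sum", "3avg", "6lag")
BIANNUAL_VARIANTS = ("0lag", "6lag")


def zscore_normalise(values: pd.Series | np.ndarray) -> pd.Series:
    """Centre and scale to sample SD 1 (denominator n−1), ignoring NaNs.

    Raises :class:`DegenerateVariableError` on a constant series.
    """
    s = pd.Series(values, copy=False).astype(float)
    finite = s.dropna()
    if finite.nunique() < 2:
        raise DegenerateVariableError(
            "series is constant (fewer than 2 distinct finite values)"
        )
    return (s - finite.mean()) / finite.std(ddof=1)


def interpolate_biannual_to_monthly(
    series: pd.Series, months: pd.PeriodIndex
) -> pd.Series:
    """Linearly interpolate January/July observations onto a monthly index.

    Interpolation is linear in the calendar-month index between adjacent
    observations; observed months are returned unchanged and no value is
    extrapolated beyond the first/last observation.
    """
    obs = series.dropna()
    if len(obs) < 2:
        raise InterpolationError(
            f"need at least 2 biannual observations to interpolate, got {len(obs)}"
        )
    out = series.reindex(months).astype(float)
    return out.interpolate(method="linear", limit_area="inside")


def aggregate_monthly_to_biannual(series: pd.Series) -> pd.Series:
    """Mean of the 6 months ending at each January/July observation month.

    A window containing any missing month yields a missing biannual value.
    """
    s = series.astype(float)
    roll = s.rolling(window=6, min_periods=6).mean()
    keep = np.isin(s.index.month, BIANNUAL_MONTHS)
    return roll[keep]


def make_variant(series: pd.Series, kind: str, cadence: str = "monthly") -> pd.Series:
    """Derive a lag/window variant of a series.

    monthly cadence: ``0lag`` identity, ``1lag``/``6lag`` shift by 1/6 months,
    ``3sum``/``3avg`` sum/mean of months t−1..t−3 (current month excluded).
    biannual cadence: ``0lag`` identity, ``6lag`` shift by one biannual
    period.  Leading undefined entries become missing.
    """
    valid = MONTHLY_VARIANTS if cadence == "monthly" else BIANNUAL_VARIANTS
    if kind not in valid:
        raise VariantError(
            f"variant {kind!r} is not defined for {cadence} cadence "
            f"(valid: {valid})"
        )
    if kind == "0lag":
        return series.copy()
    if kind == "1lag":
        return series.shift(1)
    if kind == "6lag":
        return series.shift(6 if cadence == "monthly" else 1)
    window = series.shift(1).rolling(window=3, min_periods=3)
    return window.sum() if kind == "3sum" else window.mean()


def prune_correlated(
    table: pd.DataFrame, threshold: float = 0.9, columns: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Drop columns until all pairwise |Pearson r| ≤ threshold.

    From each offending pair the column with more missing values is dropped
    (tie → the later one in column order).  Returns the pruned table and a
    list of (dropped, kept, r) triples.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if len(cols) < 2:
        return table, []
    dropped: list[tuple[str, str, float]] = []
    active = list(cols)
    while True:
        corr = table[active].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        r_max = corr.values.max()
        if r_max <= threshold or np.isnan(r_max):
            break
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        na_a, na_b = table[a].isna().sum(), table[b].isna().sum()
        out = a if na_a > na_b else b if na_b > na_a else max(
            (a, b), key=active.index
        )
        keep = b if out == a else a
        dropped.append((out, keep, float(table[a].corr(table[b]))))
        logger.warning(
            "pruning %r (|r|=%.3f with %r, threshold %.2f)", out, r_max, keep, threshold
        )
        active.remove(out)
    return table.drop(columns=[d for d, _, _ in dropped]), dropped


def spatial_interpolate(
    values: pd.Series, adjacency: dict[int, list[int]]
) -> pd.Series:
    """Fill missing district values from the mean of observed neighbours.

    Districts with no observed neighbour fall back to the national mean of
    observed districts.  Observed values are never altered.
    """
    observed = values.dropna()
    if observed.empty:
        raise InterpolationError("no observed district values to interpolate from")
    national = observed.mean()
    out = values.copy().astype(float)
    for d in values.index[values.isna()]:
        neigh = [n for n in adjacency.get(int(d), []) if n in observed.index]
        out[d] = observed[neigh].mean() if neigh else national
    return out


@dataclass
class PreprocessConfig:
    """Options controlling table construction."""

    correlation_threshold: float = 0.9
    #: per-monthly-variable 3-month window kind ('3sum' or '3avg')
    window_kind: dict[str, str] = field(
        default_factory=lambda: {"conflicts": "3sum", "rainfall": "3sum", "ndvi": "3avg"}
    )
    #: variables to spatially interpolate when district gaps exist
    spatial_fill: tuple[str, ...] = ("crop_diversity", "crop_production")
    #: normalise covariate variants over the full sample (relationship table)
    normalise_monthly: bool = True


@dataclass
class AnalysisTable:
    """Wide analysis-ready table plus bookkeeping.

    ``frame`` rows are (district, region, time point); ``cadence`` is
    'monthly' or 'biannual'.  Retained rows are complete (no missing values).
    """

    frame: pd.DataFrame
    cadence: str
    dropped_rows: int = 0

    @property
    def feature_columns(self) -> list[str]:
        reserved = {"district_id", "region_id", "date", "period", "gam"}
        return [c for c in self.frame.columns if c not in reserved]

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        if "date" in out:
            out["date"] = out["date"].astype(str)
        out.to_csv(path, index=False)


def _monthly_cadence_vars(panel: PanelDataset) -> tuple[list[str], list[str]]:
    """Split panel variables (excluding gam) into monthly vs biannual cadence."""
    monthly, biannual = [], []
    for var in panel.variables():
        if var == "gam":
            continue
        months_seen = panel.data.loc[panel.data["variable"] == var, "date"]
        if np.isin(months_seen.dt.month.unique(), BIANNUAL_MONTHS).all():
            biannual.append(var)
        else:
            monthly.append(var)
    return monthly, biannual


def build_tables(
    panel: PanelDataset,
    config: PreprocessConfig | None = None,
    adjacency: dict[int, list[int]] | None = None,
) -> tuple[AnalysisTable, AnalysisTable, dict[str, int]]:
    """Build the monthly (relationship) and biannual (forecasting) tables.

    Monthly table: biannual series (including GAM) are linearly interpolated
    to monthly cadence; derived variants are added (0lag/1lag + 3-month
    window for monthly covariates, 0lag/6lag for interpolated biannual ones,
    6lag for GAM); covariate variants are z-scored over the full sample; rows
    with any missing value are dropped.

    Biannual table: monthly covariates are averaged over the 6 months ending
    at each survey month; every variable contributes its value at the
    previous biannual period (the 6-month lag used for forecasting); any
    district missing ≥1 biannual GAM observation is dropped entirely.

    ``counts`` reports potential and retained observation numbers at each
    step.
    """
    config = config or PreprocessConfig()
    dates = panel.data["date"]
    months = pd.period_range(dates.min(), dates.max(), freq="M")
    bmonths = months[np.isin(months.month, BIANNUAL_MONTHS)]
    districts = np.sort(panel.data["district_id"].unique())
    region_of = panel.district_region_map()

    counts: dict[str, int] = {
        "potential_monthly": len(districts) * len(months),
        "potential_biannual": len(districts) * len(bmonths),
    }

    monthly_vars, biannual_vars = _monthly_cadence_vars(panel)

    # months × districts value matrices per variable
    wide: dict[str, pd.DataFrame] = {
        v: panel.wide(v).reindex(index=months, columns=districts)
        for v in ["gam", *monthly_vars, *biannual_vars]
    }

    # spatial interpolation for district-gapped variables (crop data style)
    if adjacency is not None:
        for var in config.spatial_fill:
            if var in wide:
                w = wide[var]
                gap_districts = w.columns[w.isna().all(axis=0)]
                if len(gap_districts):
                    for m in bmonths:
                        wide[var].loc[m] = spatial_interpolate(w.loc[m], adjacency)

    # ---- monthly (relationship) table -------------------------------------
    def interp_all(w: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for d in w.columns:
            obs = w[d].dropna()
            if len(obs) < 2:
                cols[d] = pd.Series(np.nan, index=months)
            else:
                cols[d] = interpolate_biannual_to_monthly(w[d], months)
        return pd.DataFrame(cols)

    monthly_frames: dict[str, pd.DataFrame] = {"gam": interp_all(wide["gam"])}
    variant_cols: dict[str, pd.DataFrame] = {}
    variant_cols["gam__6lag"] = monthly_frames["gam"].shift(6)
    for var in monthly_vars:
        w = wide[var]
        variant_cols[f"{var}__0lag"] = w
        variant_cols[f"{var}__1lag"] = w.shift(1)
        kind = config.window_kind.get(var, "3avg")
        roll = w.shift(1).rolling(3, min_periods=3)
        variant_cols[f"{var}__{kind}"] = roll.sum() if kind == "3sum" else roll.mean()
    for var in biannual_vars:
        wi = interp_all(wide[var])
        variant_cols[f"{var}__0lag"] = wi
        variant_cols[f"{var}__6lag"] = wi.shift(6)

    def melt(name: str, w: pd.DataFrame) -> pd.Series:
        s = w.stack(future_stack=True)
        s.name = name
        return s

    monthly = pd.concat(
        [melt("gam", monthly_frames["gam"])]
        + [melt(k, v) for k, v in variant_cols.items()],
        axis=1,
    )
    monthly.index.names = ["date", "district_id"]
    monthly = monthly.reset_index()
    monthly.insert(2, "region_id", monthly["district_id"].map(region_of))

    n_before = len(monthly)
    monthly = monthly.dropna().reset_index(drop=True)
    counts["monthly_retained"] = len(monthly)

    # correlation pruning across *base variables* (their original 0lag
    # columns); variants of one base are intentionally correlated and are
    # kept apart by the multiple-regression model structure instead
    base_cols = [c for c in monthly.columns if c.endswith("__0lag")]
    _, dropped_pairs = prune_correlated(
        monthly, threshold=config.correlation_threshold, columns=base_cols
    )
    for dropped_col, _, _ in dropped_pairs:
        base = dropped_col.rsplit("__", 1)[0]
        monthly = monthly.drop(
            columns=[c for c in monthly.columns if c.startswith(f"{base}__")]
        )
    counts["pruned_variables"] = len(dropped_pairs)

    if config.normalise_monthly:
        for col in [c for c in monthly.columns if "__" in c]:
            try:
                monthly[col] = zscore_normalise(monthly[col])
            except DegenerateVariableError:
                logger.warning("dropping constant column %r", col)
                monthly = monthly.drop(columns=[col])

    if monthly.empty:
        raise DataSufficiencyError("monthly analysis table is empty after cleaning")

    monthly_table = AnalysisTable(monthly, "monthly", dropped_rows=n_before - len(monthly))

    # ---- biannual (forecasting) table -------------------------------------
    keep = [
        d for d in districts if wide["gam"][d].reindex(bmonths).notna().all()
    ]
    counts["biannual_districts"] = len(keep)
    counts["biannual_rows"] = len(keep) * len(bmonths)
    if not keep:
        raise DataSufficiencyError(
            "no district has a complete biannual GAM series; "
            "forecasting table is empty"
        )

    bi_cols: dict[str, pd.DataFrame] = {"gam": wide["gam"].reindex(bmonths)[keep]}
    for var in monthly_vars:
        bi = pd.DataFrame(
            {d: aggregate_monthly_to_biannual(wide[var][d]) for d in keep}
        )
        bi_cols[f"{var}__6lag"] = bi.shift(1)
    for var in biannual_vars:
        bi_cols[f"{var}__6lag"] = wide[var].reindex(bmonths)[keep].shift(1)
    bi_cols["gam__6lag"] = bi_cols["gam"].shift(1)

    biannual = pd.concat([melt(k, v) for k, v in bi_cols.items()], axis=1)
    biannual.index.names = ["date", "district_id"]
    biannual = biannual.reset_index()
    biannual.insert(2, "region_id", biannual["district_id"].map(region_of))
    period_of = {m: i + 1 for i, m in enumerate(bmonths)}
    biannual.insert(1, "period", biannual["date"].map(period_of))

    # keep the kept-district × period frame; lag-trimming happens at feature
    # assembly so the row bookkeeping here matches the survey table
    biannual_table = AnalysisTable(biannual, "biannual")

    return monthly_table, biannual_table, counts
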