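"""Tree-ensemble forecasting of the 6-month-ahead change in GAM.

The target is the change ΔGAM(t) = GAM(t) − GAM(t−1) between consecutive
biannual survey rounds (6 months apart), in percentage points.  Features are
exclusively 6-month-lagged (previous-round) values of the selected
covariates plus the lagged GAM level itself, so nothing unavailable at
forecast time enters the model.

Time-series cross-validation: with T biannual periods, the first β periods
train the model, period β+1 is the validation set for hyperparameter grid
search, and the final two periods {T−1, T} are the test set.  The procedure
runs for two values of β and the test predictions are averaged.  Benchmarks:
the naive forecast (predicted change 0) and simple exponential smoothing
F_{t+1} = α·Y_t + (1−α)·F_t with α tuned on the validation period; SES with
α = 1 reduces exactly to the naive forecast.

Feature normalisation statistics are computed on the training rows only and
applied unchanged to validation and test rows (a ``full_sample`` flag
reproduces pre-split normalisation instead).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import ParameterGrid

from gamcast.errors import (
    ConfigurationError,
    DataSufficiencyError,
    SplitError,
    TuningError,
)

logger = logging.getLogger(__name__)

METHODS = ("random_forest", "gradient_boosting", "ses", "naive")


@dataclass(frozen=True)
class SplitPlan:
    """Chronological train / validation / test partition of period indices."""

    beta: int
    train: tuple[int, ...]
    validation: int
    test: tuple[int, int]
    total: int


def make_split_plan(total_periods: int, beta: int) -> SplitPlan:
    """Train on periods 1..β, validate on β+1, test on the last two.

    With β below T−3 the periods between validation and test are left
    unused rather than leaked into training.
    """
    if beta < 1:
        raise SplitError(f"beta must be ≥1, got {beta}")
    if beta + 1 >= total_periods - 1:
        raise SplitError(
            f"no room for validation + 2 test periods with T={total_periods}, "
            f"beta={beta}"
        )
    return SplitPlan(
        beta=beta,
        train=tuple(range(1, beta + 1)),
        validation=beta + 1,
        test=(total_periods - 1, total_periods),
        total=total_periods,
    )


@dataclass
class FeatureMatrix:
    """Feature rows (district, period) with 6-month-lag columns and ΔGAM target."""

    frame: pd.DataFrame
    feature_columns: list[str]
    dropped_rows: int = 0


def assemble_features(
    biannual: pd.DataFrame, selected: list[str]
) -> FeatureMatrix:
    """Build the design: lagged features and the change target.

    ``selected`` lists base variable names; each contributes its ``__6lag``
    column.  The lagged GAM level always enters.  Any explicitly selected
    non-lagged column is rejected (contemporaneous information would leak
    future data into the forecast).
    """
    bad = [v for v in selected if "__" in v and not v.endswith("__6lag")]
    if bad:
        raise ConfigurationError(
            f"only 6-month-lag features are allowed, got {bad}"
        )
    feature_cols = ["gam__6lag"]
    for var in selected:
        col = var if var.endswith("__6lag") else f"{var}__6lag"
        if col != "gam__6lag" and col in biannual.columns:
            feature_cols.append(col)

    frame = biannual.sort_values(["district_id", "period"]).copy()
    frame["dgam"] = frame.groupby("district_id")["gam"].diff()

    n_before = len(frame)
    frame = frame.dropna(subset=feature_cols + ["dgam"]).reset_index(drop=True)
    if frame.empty:
        raise DataSufficiencyError("no usable rows after lag/difference trimming")
    return FeatureMatrix(frame, feature_cols, dropped_rows=n_before - len(frame))


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 300, 500],
        "max_features": ["sqrt", 0.33, 1.0],
        "min_samples_split": [2, 5, 10],
    },
    "gradient_boosting": {
        "n_estimators": [100, 300, 500],
        "max_features": ["sqrt", 0.33, 1.0],
        "min_samples_split": [2, 5, 10],
        "max_depth": [2, 3, 5],
        "learning_rate": [0.01, 0.05, 0.1],
    },
}

_SIZE_KEYS = ("n_estimators", "max_depth", "min_samples_split", "learning_rate")


def _model_size_key(params: dict) -> tuple:
    """Tie-break order: prefer the smaller/simpler model."""
    return tuple(
        (params.get(k, 0) if k != "min_samples_split" else -params.get(k, 0))
        for k in _SIZE_KEYS
    )


@dataclass
class FittedForecaster:
    method: str
    model: object
    params: dict
    feature_columns: list[str]
    center: pd.Series
    scale: pd.Series
    validation_mae: float

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        X = (rows[self.feature_columns] - self.center) / self.scale
        return self.model.predict(X.to_numpy())


def _make_estimator(method: str, params: dict, seed: int):
    if method == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if method == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **params)
    raise ConfigurationError(f"unknown tree method {method!r}")


def tune_and_fit(
    method: str,
    features: FeatureMatrix,
    plan: SplitPlan,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    refit_with_validation: bool = False,
    normalise_full_sample: bool = False,
) -> FittedForecaster:
    """Grid-search on the validation period, refit, return the chosen model.

    For every grid point the model is fitted on the training periods and
    scored by MAE on the validation period; the minimiser wins, with ties
    broken toward the smaller model.  The final refit uses the training
    periods only unless ``refit_with_validation``.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[method]
    frame = features.frame
    cols = features.feature_columns
    train = frame[frame["period"].isin(plan.train)]
    val = frame[frame["period"] == plan.validation]
    if train.empty or val.empty:
        raise DataSufficiencyError("empty training or validation rows for the plan")

    norm_rows = frame if normalise_full_sample else train
    center = norm_rows[cols].mean()
    scale = norm_rows[cols].std(ddof=1).replace(0.0, 1.0)

    Xtr = ((train[cols] - center) / scale).to_numpy()
    ytr = train["dgam"].to_numpy()
    Xva = ((val[cols] - center) / scale).to_numpy()
    yva = val["dgam"].to_numpy()

    results: list[tuple[float, tuple, dict]] = []
    for params in ParameterGrid(grid):
        try:
            est = _make_estimator(method, params, seed)
            est.fit(Xtr, ytr)
            mae = float(np.mean(np.abs(est.predict(Xva) - yva)))
        except Exception as exc:  # noqa: BLE001 - a bad grid point is skippable
            logger.warning("grid point %s failed: %s", params, exc)
            continue
        results.append((mae, _model_size_key(params), params))
    if not results:
        raise TuningError(f"every grid point failed for {method}")

    results.sort(key=lambda t: (t[0], t[1]))
    best_mae, _, best_params = results[0]

    refit_rows = (
        pd.concat([train, val]) if refit_with_validation else train
    )
    Xf = ((refit_rows[cols] - center) / scale).to_numpy()
    model = _make_estimator(method, best_params, seed)
    model.fit(Xf, refit_rows["dgam"].to_numpy())
    return FittedForecaster(
        method, model, dict(best_params), cols, center, scale, best_mae
    )


# ---------------------------------------------------------------------------
# benchmarks


def ses_forecast(series: np.ndarray, alpha: float) -> np.ndarray:
    """Simple exponential smoothing forecasts F_2..F_{T+1}.

    F_1 is initialised to Y_1; F_{t+1} = α·Y_t + (1−α)·F_t.  Returns the
    array [F_2, …, F_{T+1}] of one-step-ahead forecasts (the last entry is
    the out-of-sample forecast).  α = 1 reproduces the naive forecast.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must lie in [0,1], got {alpha}")
    y = np.asarray(series, float)
    if y.size < 1:
        raise DataSufficiencyError("SES needs at least one observation")
    out = np.empty(y.size)
    f = y[0]
    for t in range(y.size):
        f = alpha * y[t] + (1.0 - alpha) * f
        out[t] = f
    return out


def naive_forecast(series: np.ndarray) -> float:
    """Forecast = last observed value (implied predicted change 0)."""
    y = np.asarray(series, float)
    if y.size < 1:
        raise DataSufficiencyError("naive forecast needs at least one observation")
    return float(y[-1])


def _ses_changes(
    gam_wide: pd.DataFrame, alpha: float, periods: list[int]
) -> pd.DataFrame:
    """Predicted change per district for the requested periods.

    ``gam_wide`` is periods × districts.  The predicted change for period t
    is F_t − Y_{t−1} with F computed from observations up to t−1.
    """
    preds = {}
    idx = list(gam_wide.index)
    for d in gam_wide.columns:
        y = gam_wide[d].to_numpy(float)
        f = ses_forecast(y, alpha)  # f[k] = forecast for period idx[k]+1
        row = {}
        for t in periods:
            k = idx.index(t)
            row[t] = f[k - 1] - y[k - 1]  # forecast made at t−1 minus last actual
        preds[d] = row
    return pd.DataFrame(preds).T  # districts × periods


@dataclass
class ForecastConfig:
    betas: tuple[int, ...] = (5, 6)
    grids: dict[str, dict[str, list]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()}
    )
    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    refit_with_validation: bool = False
    normalise_full_sample: bool = False
    methods: tuple[str, ...] = METHODS


@dataclass
class ForecastSet:
    """Per (district, period, method, β) predictions plus the β-averaged view."""

    per_beta: pd.DataFrame  # district_id, period, method, beta, predicted, actual
    chosen: dict  # per (method, beta): hyperparameters / alpha

    def averaged(self) -> pd.DataFrame:
        keys = ["district_id", "period", "method"]
        out = (
            self.per_beta.groupby(keys, as_index=False)
            .agg(predicted_change=("predicted_change", "mean"),
                 actual_change=("actual_change", "mean"))
        )
        return out

    def to_csv(self, path) -> None:
        self.per_beta.to_csv(path, index=False)

    def chosen_to_json(self, path) -> None:
        payload = {
            f"{m}__beta{b}": v for (m, b), v in self.chosen.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def run_forecast_suite(
    biannual: pd.DataFrame,
    selected: list[str],
    config: ForecastConfig | None = None,
    seed: int = 0,
) -> ForecastSet:
    """Run every method for every β and collect test-period predictions."""
    config = config or ForecastConfig()
    features = assemble_features(biannual, selected)
    total = int(biannual["period"].max())

    gam_wide = biannual.pivot_table(
        index="period", columns="district_id", values="gam"
    )

    records = []
    chosen: dict = {}
    for beta in config.betas:
        plan = make_split_plan(total, beta)
        test_rows = features.frame[features.frame["period"].isin(plan.test)]
        actual = test_rows.set_index(["district_id", "period"])["dgam"]

        for method in config.methods:
            if method in ("random_forest", "gradient_boosting"):
                fitted = tune_and_fit(
                    method,
                    features,
                    plan,
                    grid=config.grids.get(method),
                    seed=seed,
                    refit_with_validation=config.refit_with_validation,
                    normalise_full_sample=config.normalise_full_sample,
                )
                pred = pd.Series(
                    fitted.predict(test_rows),
                    index=actual.index,
                )
                chosen[(method, beta)] = fitted.params
            elif method == "ses":
                # tune alpha on the validation period
                val_periods = [plan.validation]
                hist = gam_wide.loc[: plan.validation]
                best = None
                for alpha in config.alpha_grid:
                    p = _ses_changes(hist, alpha, val_periods)
                    act = (
                        features.frame[
                            features.frame["period"] == plan.validation
                        ].set_index("district_id")["dgam"]
                    )
                    common = act.index.intersection(p.index)
                    mae = float(
                        np.mean(np.abs(p.loc[common, plan.validation] - act[common]))
                    )
                    if best is None or mae < best[0] or (
                        mae == best[0] and alpha < best[1]
                    ):
                        best = (mae, alpha)
                alpha = best[1]
                chosen[(method, beta)] = {"alpha": float(alpha)}
                p = _ses_changes(gam_wide, alpha, list(plan.test))
                pred = pd.Series(
                    {
                        (d, t): p.loc[d, t]
                        for d, t in actual.index
                    }
                )
            else:  # naive
                pred = pd.Series(0.0, index=actual.index)
                chosen[(method, beta)] = {}

            for (district, period), a in actual.items():
                records.append(
                    {
                        "district_id": district,
                        "period": period,
                        "method": method,
                        "beta": beta,
                        "predicted_change": float(pred[(district, period)]),
                        "actual_change": float(a),
                    }
                )

    return ForecastSet(pd.DataFrame(records), chosen)
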