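"""Forecast scoring: MAE, direction quadrants, per-district errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gamcast.errors import DataSufficiencyError


def mae(predicted, actual) -> float:
    """Mean absolute error in percentage points of GAM."""
    p = np.asarray(predicted, float)
    a = np.asarray(actual, float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise DataSufficiencyError("MAE of an empty forecast set is undefined")
    return float(np.mean(np.abs(p - a)))


@dataclass
class QuadrantSummary:
    """Predicted-vs-actual direction breakdown, in % of non-tied observations.

    true_increase: predicted up, actually up; false_increase: predicted up,
    actually down; and so on.  Exact zero changes (possible in synthetic
    data) are excluded from the denominator and counted in ``ties_excluded``.
    """

    true_increase_pct: float
    true_decrease_pct: float
    false_increase_pct: float
    false_decrease_pct: float
    ties_excluded: int

    def as_dict(self) -> dict[str, float]:
        return {
            "true_increase_pct": self.true_increase_pct,
            "true_decrease_pct": self.true_decrease_pct,
            "false_increase_pct": self.false_increase_pct,
            "false_decrease_pct": self.false_decrease_pct,
            "ties_excluded": self.ties_excluded,
        }


def quadrant_breakdown(predicted, actual) -> QuadrantSummary:
    p = np.asarray(predicted, float)
    a = np.asarray(actual, float)
    tie = (p == 0) | (a == 0)
    p, a = p[~tie], a[~tie]
    if p.size == 0:
        raise DataSufficiencyError("all observations are ties; quadrants undefined")
    n = p.size
    up_p, up_a = p > 0, a > 0
    return QuadrantSummary(
        true_increase_pct=100.0 * np.sum(up_p & up_a) / n,
        true_decrease_pct=100.0 * np.sum(~up_p & ~up_a) / n,
        false_increase_pct=100.0 * np.sum(up_p & ~up_a) / n,
        false_decrease_pct=100.0 * np.sum(~up_p & up_a) / n,
        ties_excluded=int(tie.sum()),
    )


def direction_accuracy(q: QuadrantSummary) -> float:
    """Share of correct direction calls: the two green quadrants summed."""
    return q.true_increase_pct + q.true_decrease_pct


def per_district_mae(forecasts: pd.DataFrame, method: str) -> pd.DataFrame:
    """MAE per district for one method (β-averaged forecast frame expected).

    Districts with no test rows are simply absent from the output.
    """
    sub = forecasts[forecasts["method"] == method]
    if sub.empty:
        raise DataSufficiencyError(f"no forecasts for method {method!r}")
    err = (sub["predicted_change"] - sub["actual_change"]).abs()
    out = (
        sub.assign(abs_error=err)
        .groupby("district_id")
        .agg(mae=("abs_error", "mean"), n_test=("abs_error", "size"))
        .reset_index()
    )
    return out


def overall_metrics(forecasts: pd.DataFrame) -> pd.DataFrame:
    """MAE and direction accuracy per method over the β-averaged forecasts."""
    rows = []
    for method, sub in forecasts.groupby("method"):
        row = {
            "method": method,
            "mae": mae(sub["predicted_change"], sub["actual_change"]),
        }
        try:
            q = quadrant_breakdown(sub["predicted_change"], sub["actual_change"])
            row["direction_accuracy"] = direction_accuracy(q)
            row.update(q.as_dict())
        except DataSufficiencyError:
            # the naive benchmark predicts exactly zero change, so every one
            # of its observations is a tie and no direction call exists
            row["direction_accuracy"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
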