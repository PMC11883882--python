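"""Seeded synthetic district×time panels with known covariate→GAM links.

The generator emulates the structure of the Somalia district panel used in
food-security early-warning work: 74 districts nested in 18 regions, monthly
covariates (conflicts, rainfall anomaly, NDVI) and biannual covariates (IPC
phase-3+ share, crop diversity, crop production, population, density) over
July 2017 – July 2021, with GAM prevalence surveyed twice a year (January and
July, the post-Deyr and post-Gu survey rounds).

Every covariate is generated as a latent monthly AR(1) process with a
district-phase-jittered seasonal sinusoid, scaled to a configured mean and
standard deviation, and recorded at its cadence.  GAM is built as

    GAM_d(t) = baseline_d + Σ_j link_j( z_j,d(t − 6) ) + season_d(t) + ε_d(t)

where ``z`` is the standardised latent covariate, the links are linear,
hard-threshold or hinge (piecewise-linear kink) functions with configured
effect sizes in percentage points per covariate SD, and the 6-month lag makes
the previous-period covariates genuinely predictive of the next GAM survey.
Values are clipped to [0, 100] after noise.  The ground truth (link nature
and generating coefficients per variable) is returned alongside the panel so
downstream classifiers and forecasters can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from gamcast.errors import ConfigurationError

Cadence = Literal["monthly", "biannual"]
Link = Literal["linear", "threshold", "hinge", "none"]

_VALID_CADENCES = ("monthly", "biannual")
_VALID_LINKS = ("linear", "threshold", "hinge", "none")

#: months at which biannual surveys are observed (January and July)
BIANNUAL_MONTHS = (1, 7)

#: months by which covariate links lead GAM
LINK_LAG_MONTHS = 6


@dataclass
class VariableDef:
    """Definition of one covariate: cadence, moments and its link to GAM.

    ``mean``/``sd`` are in the variable's native units; ``effect_size`` is in
    percentage points of GAM per standard deviation of the (standardised)
    latent covariate; ``threshold_location`` is in covariate SD units.
    """

    name: str
    cadence: Cadence = "monthly"
    mean: float = 0.0
    sd: float = 1.0
    link: Link = "none"
    effect_size: float = 0.0
    threshold_location: float = 0.0

    def __post_init__(self) -> None:
        if self.cadence not in _VALID_CADENCES:
            raise ConfigurationError(
                f"variable {self.name!r}: invalid cadence {self.cadence!r} "
                f"(expected one of {_VALID_CADENCES})"
            )
        if self.link not in _VALID_LINKS:
            raise ConfigurationError(
                f"variable {self.name!r}: invalid link {self.link!r} "
                f"(expected one of {_VALID_LINKS})"
            )
        if not np.isfinite(self.effect_size):
            raise ConfigurationError(
                f"variable {self.name!r}: effect_size must be finite"
            )


def default_variable_defs() -> list[VariableDef]:
    """Default covariates with the field-reported district-level moments.

    Means/SDs follow the published summary statistics of the Somalia panel
    (e.g. rainfall anomaly mean −1.2 mm, SD 25.1 mm).  Default links: NDVI
    acts linearly on GAM, IPC share and crop diversity act through hinge /
    threshold nonlinearities, rainfall anomaly through a hinge (droughts
    matter, surpluses saturate); the remaining covariates are null links so
    false-selection behaviour is observable.
    """
    return [
        VariableDef("conflicts", "monthly", 5.6, 9.1, "none", 0.0),
        VariableDef("rainfall", "monthly", -1.2, 25.1, "hinge", -1.2, -0.25),
        VariableDef("ndvi", "monthly", 0.3, 0.1, "linear", -1.5),
        VariableDef("ipc", "biannual", 0.14, 0.11, "hinge", 1.5, 0.25),
        VariableDef("crop_diversity", "biannual", 2.1, 1.6, "threshold", -1.2, 0.0),
        VariableDef("crop_production", "biannual", 434.4, 658.8, "none", 0.0),
        VariableDef("population", "biannual", 167638.4, 253802.4, "none", 0.0),
        VariableDef("density", "biannual", 147.5, 1059.5, "none", 0.0),
    ]


@dataclass
class PanelSpec:
    """Full configuration of a synthetic panel."""

    n_districts: int = 74
    n_regions: int = 18
    start_month: str = "2017-07"
    end_month: str = "2021-07"
    variable_defs: list[VariableDef] = field(default_factory=default_variable_defs)
    baseline_gam: float = 14.5
    gam_season_amplitude: float = 1.0
    covariate_ar: float = 0.9
    covariate_season_amplitude: float = 0.6
    noise_sd: float = 1.0
    missing_district_fraction: float = 9 / 74
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions > self.n_districts:
            raise ConfigurationError(
                f"n_regions ({self.n_regions}) cannot exceed "
                f"n_districts ({self.n_districts})"
            )
        if not 0.0 <= self.missing_district_fraction <= 1.0:
            raise ConfigurationError(
                "missing_district_fraction must lie in [0, 1], got "
                f"{self.missing_district_fraction}"
            )
        # validates cadence/link for defs supplied as plain tuples
        self.variable_defs = [
            v if isinstance(v, VariableDef) else VariableDef(*v)
            for v in self.variable_defs
        ]

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, self.end_month, freq="M")

    @property
    def biannual_months(self) -> pd.PeriodIndex:
        months = self.months
        return months[np.isin(months.month, BIANNUAL_MONTHS)]

    def district_regions(self) -> np.ndarray:
        """Region id per district: contiguous blocks, every region non-empty."""
        return (np.arange(self.n_districts) * self.n_regions) // self.n_districts


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring downstream stages.

    ``nature`` is 'linear' for a linear link, 'nonlinear' for threshold or
    hinge links, and 'null' for no link.
    """

    nature: dict[str, str]
    coefficients: dict[str, dict[str, float]]
    included: dict[int, bool]

    def active_variables(self) -> list[str]:
        return [v for v, n in self.nature.items() if n != "null"]

    def to_json(self, path) -> None:
        payload = {
            "nature": self.nature,
            "coefficients": self.coefficients,
            "included": {str(k): v for k, v in self.included.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            nature=payload["nature"],
            coefficients=payload["coefficients"],
            included={int(k): v for k, v in payload["included"].items()},
        )


_NATURE_BY_LINK = {
    "linear": "linear",
    "threshold": "nonlinear",
    "hinge": "nonlinear",
    "none": "null",
}


def apply_link(
    z: np.ndarray, link: Link, effect_size: float, threshold_location: float = 0.0
) -> np.ndarray:
    """Evaluate a covariate→GAM link on standardised covariate values.

    linear:    effect·z
    threshold: effect·1[z > loc]   (hard step)
    hinge:     effect·max(z − loc, 0)   (piecewise-linear kink)
    none:      0
    """
    z = np.asarray(z, dtype=float)
    if link == "linear":
        return effect_size * z
    if link == "threshold":
        return effect_size * (z > threshold_location).astype(float)
    if link == "hinge":
        return effect_size * np.maximum(z - threshold_location, 0.0)
    if link == "none":
        return np.zeros_like(z)
    raise ConfigurationError(f"invalid link {link!r}")


@dataclass
class PanelDataset:
    """Long-format district×month observations of named variables.

    ``data`` columns: district_id, region_id, date (pandas monthly Period),
    variable, value.  (district, date, variable) is unique.
    """

    data: pd.DataFrame

    COLUMNS = ("district_id", "region_id", "date", "variable", "value")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ConfigurationError(f"panel missing columns: {sorted(missing)}")

    def wide(self, variable: str) -> pd.DataFrame:
        """Months × districts matrix for one variable."""
        sub = self.data[self.data["variable"] == variable]
        return sub.pivot(index="date", columns="district_id", values="value")

    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    def district_region_map(self) -> pd.Series:
        pairs = self.data[["district_id", "region_id"]].drop_duplicates()
        return pairs.set_index("district_id")["region_id"].sort_index()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["date"] = out["date"].astype(str)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        raw = pd.read_csv(path)
        raw["date"] = pd.PeriodIndex(raw["date"], freq="M")
        return cls(raw)


def ring_adjacency(spec: PanelSpec) -> dict[int, list[int]]:
    """Simple synthetic district adjacency: each district borders its two
    index-neighbours within the panel ordering (a ring).  Stands in for a
    shapefile-derived adjacency, which is out of scope here."""
    n = spec.n_districts
    return {d: [(d - 1) % n, (d + 1) % n] for d in range(n)}


def _latent_covariates(spec: PanelSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Standardised latent monthly paths, one (n_months × n_districts) array
    per variable.  AR(1) in time with stationary unit variance, plus a
    seasonal sinusoid with per-district phase jitter, rescaled to unit SD."""
    months = spec.months
    n_t, n_d = len(months), spec.n_districts
    phi = spec.covariate_ar
    amp = spec.covariate_season_amplitude
    t_month = months.month.to_numpy()  # calendar month 1..12

    out: dict[str, np.ndarray] = {}
    for vdef in spec.variable_defs:
        innov_sd = np.sqrt(1.0 - phi**2)
        z = np.empty((n_t, n_d))
        z[0] = rng.normal(0.0, 1.0, n_d)
        shocks = rng.normal(0.0, innov_sd, (n_t - 1, n_d))
        for t in range(1, n_t):
            z[t] = phi * z[t - 1] + shocks[t - 1]
        phase = rng.uniform(0, 2 * np.pi, n_d)
        season = amp * np.sin(2 * np.pi * t_month[:, None] / 12.0 + phase[None, :])
        combined = z + season
        # rescale so the configured sd is the sd of the recorded variable
        total_sd = np.sqrt(1.0 + amp**2 / 2.0)
        out[vdef.name] = combined / total_sd
    return out


def generate_panel(spec: PanelSpec) -> tuple[PanelDataset, GroundTruth]:
    """Generate a complete panel (before missingness) and its ground truth.

    Deterministic for a fixed ``spec.seed``.  GAM is recorded at biannual
    months only; monthly covariates at every month; biannual covariates at
    January/July only.
    """
    rng = np.random.default_rng([spec.seed, 0])
    months = spec.months
    n_d = spec.n_districts
    regions = spec.district_regions()
    latent = _latent_covariates(spec, rng)

    # district baselines around the configured national mean
    baseline = spec.baseline_gam + rng.normal(0.0, 1.5, n_d)
    phase = rng.uniform(0, 2 * np.pi, n_d)
    t_month = months.month.to_numpy()
    season_gam = spec.gam_season_amplitude * np.sin(
        2 * np.pi * t_month[:, None] / 12.0 + phase[None, :]
    )

    contrib = np.zeros((len(months), n_d))
    for vdef in spec.variable_defs:
        z = latent[vdef.name]
        lagged = np.full_like(z, np.nan)
        lagged[LINK_LAG_MONTHS:] = z[:-LINK_LAG_MONTHS] if LINK_LAG_MONTHS else z
        lagged[:LINK_LAG_MONTHS] = z[0]  # warm-up: hold the initial state
        contrib += apply_link(
            lagged, vdef.link, vdef.effect_size, vdef.threshold_location
        )

    noise = rng.normal(0.0, spec.noise_sd, (len(months), n_d))
    gam = baseline[None, :] + contrib + season_gam + noise
    gam = np.clip(gam, 0.0, 100.0)

    records: list[pd.DataFrame] = []

    def _block(var: str, values: np.ndarray, keep: np.ndarray) -> pd.DataFrame:
        dates = np.repeat(months[keep], n_d)
        return pd.DataFrame(
            {
                "district_id": np.tile(np.arange(n_d), keep.sum()),
                "region_id": np.tile(regions, keep.sum()),
                "date": dates,
                "variable": var,
                "value": values[keep].ravel(),
            }
        )

    biannual_mask = np.isin(months.month, BIANNUAL_MONTHS)
    all_mask = np.ones(len(months), dtype=bool)

    records.append(_block("gam", gam, biannual_mask))
    for vdef in spec.variable_defs:
        native = vdef.mean + vdef.sd * latent[vdef.name]
        mask = all_mask if vdef.cadence == "monthly" else biannual_mask
        records.append(_block(vdef.name, native, mask))

    panel = PanelDataset(pd.concat(records, ignore_index=True))

    truth = GroundTruth(
        nature={v.name: _NATURE_BY_LINK[v.link] for v in spec.variable_defs},
        coefficients={
            v.name: {
                "effect_size": v.effect_size,
                "threshold_location": v.threshold_location,
                "mean": v.mean,
                "sd": v.sd,
            }
            for v in spec.variable_defs
        },
        included={d: True for d in range(n_d)},
    )
    return panel, truth


def inject_missingness(
    panel: PanelDataset, spec: PanelSpec, truth: GroundTruth | None = None
) -> PanelDataset:
    """Remove biannual GAM values for a seeded random fraction of districts.

    Each affected district loses at least one (1–3) of its biannual GAM
    observations; covariates are untouched.  When a ``truth`` is supplied its
    ``included`` flags are updated in place (these districts drop out of the
    biannual analysis table downstream)."""
    if not 0.0 <= spec.missing_district_fraction <= 1.0:
        raise ConfigurationError(
            f"missing fraction must lie in [0,1], got {spec.missing_district_fraction}"
        )
    n_missing = int(round(spec.missing_district_fraction * spec.n_districts))
    if n_missing == 0:
        return panel

    rng = np.random.default_rng([spec.seed, 1])
    victims = rng.choice(spec.n_districts, size=n_missing, replace=False)
    bmonths = spec.biannual_months

    data = panel.data
    drop_mask = np.zeros(len(data), dtype=bool)
    is_gam = (data["variable"] == "gam").to_numpy()
    for d in victims:
        k = int(rng.integers(1, min(3, len(bmonths)) + 1))
        lost = rng.choice(len(bmonths), size=k, replace=False)
        lost_months = set(bmonths[lost])
        mask = (
            is_gam
            & (data["district_id"] == d).to_numpy()
            & data["date"].isin(lost_months).to_numpy()
        )
        drop_mask |= mask
        if truth is not None:
            truth.included[int(d)] = False

    return PanelDataset(data[~drop_mask].reset_index(drop=True))
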