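"""Run configuration: defaults, validation, YAML/JSON round-trip.

Every analysis constant (the 0.9 correlation-pruning threshold, the
0.01/0.05/0.3 p-value thresholds, the 95% band level, the 50% regional
linearity rule, the β set, the 6-month forecast horizon, the two test
periods) lives here as a named default rather than being hard-coded in the
stage code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from gamcast.errors import ConfigurationError


@dataclass
class RunConfig:
    # paths
    panel_csv: str = "panel.csv"
    adjacency_json: str = "adjacency.json"
    output_dir: str = "outputs"

    # synthetic generation
    n_districts: int = 74
    n_regions: int = 18
    start_month: str = "2017-07"
    end_month: str = "2021-07"
    missing_district_fraction: float = 9 / 74
    seed: int = 0

    # preprocessing
    correlation_threshold: float = 0.9
    normalise_monthly: bool = True

    # relationship analysis
    grid_size: int = 100
    trim_quantiles: tuple[float, float] = (0.05, 0.95)
    bandwidth_multiplier: float = 1.0
    band_level: float = 0.95
    simultaneous_ols_band: bool = True
    region_linear_share: float = 0.5
    p_thresholds: tuple[float, float, float] = (0.01, 0.05, 0.3)
    newey_west_lags: int | None = None  # None → plug-in rule
    compute_nature: bool = True

    # forecasting
    betas: tuple[int, ...] = (5, 6)
    alpha_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    refit_with_validation: bool = False
    normalise_full_sample: bool = False
    grids: dict = field(default_factory=dict)  # empty → library defaults

    def validate(self) -> None:
        problems = []
        t = self.p_thresholds
        if not (0 < t[0] < t[1] < t[2] < 1):
            problems.append(
                f"p_thresholds must be strictly increasing inside (0,1), got {t}"
            )
        if not 0 < self.correlation_threshold <= 1:
            problems.append(
                f"correlation_threshold must lie in (0,1], got "
                f"{self.correlation_threshold}"
            )
        if not 0 <= self.missing_district_fraction <= 1:
            problems.append("missing_district_fraction must lie in [0,1]")
        if not 0 < self.band_level < 1:
            problems.append(f"band_level must lie in (0,1), got {self.band_level}")
        lo, hi = self.trim_quantiles
        if not 0 <= lo < hi <= 1:
            problems.append(f"trim_quantiles must be ordered in [0,1], got {lo},{hi}")
        if any(not 0 <= a <= 1 for a in self.alpha_grid):
            problems.append("alpha_grid values must lie in [0,1]")
        if problems:
            raise ConfigurationError(
                "invalid configuration:\n  - " + "\n  - ".join(problems)
            )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON (YAML is a JSON superset; both parse)."""
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trim_quantiles", "betas", "alpha_grid", "p_thresholds"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
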