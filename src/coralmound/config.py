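"""Pipeline configuration: flat key-value YAML, validated, defaults = study values."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # input paths (any may be absent; the corresponding stage is skipped)
    useries_csv: Optional[str] = None
    foram_csv: Optional[str] = None
    ct_volume: Optional[str] = None
    ct_voi_mask: Optional[str] = None
    hydro_csv: Optional[str] = None

    # chronology
    max_age_gap_ka: float = 0.6
    max_depth_gap_cm: float = 110.0

    # Mg/Ca calibration (exponential a*exp(b*T))
    mgca_a: float = 1.24
    mgca_b: float = 0.069
    mgca_sd2_a: float = 0.04
    mgca_sd2_b: float = 0.005

    # paleotemperature equation
    paleotemp_k0: float = 3.58
    paleotemp_k1: float = -0.245
    paleotemp_k2: float = 0.0011
    paleotemp_scale_offset: float = 0.27

    # density calibrations and salinity regression
    density_calibration: str = "regional"  # regional | global
    salinity_slope: float = 0.2547
    salinity_intercept: float = -8.6493

    # site
    water_depth_m: float = 101.0

    # CT
    ct_threshold: Optional[float] = None  # None -> Otsu
    ct_min_voxels: int = 5
    ct_denoise: bool = True

    # uncertainty
    uncertainty_method: str = "delta"  # delta | mc
    monte_carlo_n: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.density_calibration not in ("regional", "global"):
            raise ConfigError("density_calibration must be 'regional' or 'global'")
        if self.uncertainty_method not in ("delta", "mc"):
            raise ConfigError("uncertainty_method must be 'delta' or 'mc'")
        if self.monte_carlo_n < 100:
            raise ConfigError("monte_carlo_n must be >= 100")
        if self.max_age_gap_ka <= 0 or self.max_depth_gap_cm <= 0:
            raise ConfigError("cluster gap parameters must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
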