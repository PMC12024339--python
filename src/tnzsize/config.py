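"""Configuration objects for the synthetic generator and the pipeline.

``SyntheticConfig`` holds every parameter of the generative model: site
geography and its link to annual mean minimum temperature (AnnMinTemp),
the gamma body-size model with sex/stage fixed effects and site/year random
intercepts, the population thermoneutral zone (TNZ) and its dependence on
AnnMinTemp, and the respirometry measurement process.  ``RunConfig`` wraps a
``SyntheticConfig`` together with per-stage analysis parameters for pipeline
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

#: Chamber-temperature schedule: every 2.5 degC from 37.5 down to 25,
#: then every 5 degC down to 5.
DEFAULT_CHAMBER_TEMPS: tuple[float, ...] = (
    37.5, 35.0, 32.5, 30.0, 27.5, 25.0, 20.0, 15.0, 10.0, 5.0,
)

STAGES: tuple[str, ...] = ("juvenile", "sub-adult", "adult I", "adult II", "old")

#: Body-mass bands (g) delimiting the five ontogenetic stages.
STAGE_BANDS: dict[str, tuple[float, float]] = {
    "juvenile": (0.0, 16.0),
    "sub-adult": (16.0, 23.0),
    "adult I": (23.0, 29.0),
    "adult II": (29.0, 37.0),
    "old": (37.0, np.inf),
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic ecophysiology data generator.

    Units are stated per field.  Slope defaults mirror the magnitudes a field
    study at this scale reports: AnnMinTemp rising ~0.89 degC per degree of
    longitude and falling ~2.32 degC per km of altitude, body length rising
    ~0.99 mm per degC, and TNZ limits moving +0.15 / -0.19 degC per degC.
    """

    # --- sites and climate ---
    n_sites: int = 9
    lon_range: tuple[float, float] = (104.5, 107.5)      # degE
    alt_range: tuple[float, float] = (0.30, 1.45)        # km
    lat_range: tuple[float, float] = (25.5, 29.0)        # degN
    temp_intercept: float = -79.8                        # degC
    temp_lon_slope: float = 0.89                         # degC per degE
    temp_alt_slope: float = -2.32                        # degC per km
    temp_year_slope: float = 0.26                        # degC per yr
    temp_noise_sd: float = 0.30                          # degC
    seasonal_amplitude: float = 8.0                      # degC, annual sinusoid
    daily_noise_sd: float = 2.0                          # degC, day-to-day
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021, 2022, 2023)

    # --- individuals ---
    n_per_site_year: int = 10
    length_intercept: float = 88.0                       # mm
    length_temp_slope: float = 0.99                      # mm per degC
    length_tnzb_slope: float = 0.0                       # mm per degC of TNZ breadth
    mass_intercept: float = 14.0                         # g
    mass_temp_slope: float = 0.44                        # g per degC
    sex_effect: tuple[float, float] = (2.0, 1.0)         # male offset (mm, g)
    stage_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "juvenile": (-12.0, -7.5),
            "sub-adult": (0.0, 0.0),
            "adult I": (5.0, 6.5),
            "adult II": (10.0, 13.5),
            "old": (15.0, 21.0),
        }
    )
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "juvenile": 0.08,
            "sub-adult": 0.27,
            "adult I": 0.30,
            "adult II": 0.25,
            "old": 0.10,
        }
    )
    site_re_sd: float = 0.8                              # response units
    year_re_sd: float = 0.4                              # response units
    gamma_shape: float = 300.0
    pregnancy_prob: float = 0.15

    # --- thermoneutral zone and respirometry ---
    tnz_base_llt: float = 27.6                           # degC
    tnz_base_ult: float = 33.9                           # degC
    tnz_llt_temp_slope: float = 0.15                     # degC per degC AnnMinTemp
    tnz_ult_temp_slope: float = -0.19                    # degC per degC AnnMinTemp
    tnz_site_sd: float = 0.15                            # degC, site-level TNZ noise
    bmr_level: float = 1.8                               # mL O2 g-1 h-1
    cold_slope: float = -0.12                            # mL O2 g-1 h-1 per degC
    warm_slope: float = 0.20                             # mL O2 g-1 h-1 per degC
    rmr_noise_sd: float = 0.05                           # mL O2 g-1 h-1
    n_rmr_animals: int = 6
    trace_minutes: int = 10
    chamber_temps: tuple[float, ...] = DEFAULT_CHAMBER_TEMPS
    rmr_mass_range: tuple[float, float] = (24.0, 34.0)   # g

    seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.chamber_temps = tuple(float(t) for t in self.chamber_temps)
        for name in ("lon_range", "alt_range", "lat_range", "rmr_mass_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} is degenerate: min {lo} > max {hi}")
            setattr(self, name, (float(lo), float(hi)))
        for name in (
            "temp_noise_sd", "daily_noise_sd", "site_re_sd", "year_re_sd",
            "tnz_site_sd", "rmr_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.gamma_shape <= 0:
            raise ConfigurationError("gamma_shape must be > 0")
        if self.tnz_base_llt >= self.tnz_base_ult:
            raise ConfigurationError("tnz_base_llt must be < tnz_base_ult")
        if self.n_sites < 2:
            raise ConfigurationError("n_sites must be >= 2")
        if not 0.0 <= self.pregnancy_prob <= 1.0:
            raise ConfigurationError("pregnancy_prob must lie in [0, 1]")
        if self.cold_slope >= 0 or self.warm_slope <= 0:
            raise ConfigurationError("cold_slope must be < 0 and warm_slope > 0")
        if set(self.stage_probs) != set(STAGES):
            raise ConfigurationError("stage_probs must cover exactly the five stages")
        total = sum(self.stage_probs.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"stage_probs must sum to 1 (got {total})")
        if self.trace_minutes < 5:
            raise ConfigurationError("trace_minutes must be >= 5")
        if not self.years:
            raise ConfigurationError("years must be non-empty")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_effects"] = {k: list(v) for k, v in self.stage_effects.items()}
        d["stage_probs"] = dict(self.stage_probs)
        for key in ("lon_range", "alt_range", "lat_range", "rmr_mass_range",
                    "years", "chamber_temps", "sex_effect"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("lon_range", "alt_range", "lat_range", "rmr_mass_range",
                    "sex_effect"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("years", "chamber_temps"):
            if key in d:
                d[key] = tuple(d[key])
        if "stage_effects" in d:
            d["stage_effects"] = {k: tuple(v) for k, v in d["stage_effects"].items()}
        return cls(**d)

    def rng(self, label: str) -> np.random.Generator:
        """A child random stream derived from the root seed and a fixed label.

        Distinct labels give statistically independent streams, so adding a
        new generation stage never perturbs existing ones.
        """
        key = zlib.crc32(label.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class RunConfig:
    """Full pipeline configuration: simulation block plus per-stage parameters."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # metabolic_tnz stage
    degree: int = 4
    delta: float = 0.03                 # mL O2 g-1 h-1 per degC derivative threshold
    window_minutes: int = 5
    # model stages
    alpha: float = 0.05
    min_days_per_year: int = 300
    spatial_years: tuple[int, int] | None = None   # default: last two config years
    seed: int | None = None             # overrides synthetic.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.seed is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=int(self.seed))
        if self.spatial_years is None:
            ys = self.synthetic.years
            self.spatial_years = (ys[-2], ys[-1]) if len(ys) >= 2 else (ys[0], ys[0])
        self.spatial_years = (int(self.spatial_years[0]), int(self.spatial_years[1]))

    def to_dict(self) -> dict:
        d = {
            "synthetic": self.synthetic.to_dict(),
            "degree": self.degree,
            "delta": self.delta,
            "window_minutes": self.window_minutes,
            "alpha": self.alpha,
            "min_days_per_year": self.min_days_per_year,
            "spatial_years": list(self.spatial_years),
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and not isinstance(d["synthetic"], SyntheticConfig):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if d.get("spatial_years") is not None:
            d["spatial_years"] = tuple(d["spatial_years"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, stamped into outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf8")
        return hashlib.sha256(blob).hexdigest()[:12]
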