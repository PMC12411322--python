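"""Declarative simulation configuration.

The configuration fixes the study conditions of the synthetic world: the
trial network geometry (locations, years, latitudes), the weather and soil
generators, the genetic panel, the true factor-analytic GEI structure whose
environmental main effects and loadings are functions of the environmental
covariates, and the trial design.  One master ``seed`` drives every stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError


@dataclass
class WeatherConfig:
    mean_temp: float = 22.0          # annual mean daily-maximum temperature, degC
    amplitude: float = 7.0           # seasonal semi-amplitude of the annual cycle, degC
    diurnal_range: float = 12.0      # tmax - tmin, degC
    noise_sd: float = 2.5            # daily AR(1) temperature noise sd, degC
    noise_ar1: float = 0.6
    lat_gradient: float = 0.55       # degC of mean temp per degree latitude northward
    annual_rain_mm: float = 420.0
    rain_seasonality: float = 0.75   # 0 = uniform, 1 = fully seasonal
    rain_shape: float = 0.8          # gamma shape of daily rain amounts
    wet_day_prob: float = 0.30       # mean daily rain probability


@dataclass
class GeneticsConfig:
    n_founders: int = 8
    n_lines: int = 80                # includes checks
    n_markers: int = 120
    block_size: int = 8              # markers per linkage block
    block_corr: float = 0.9          # founder-allele correlation within block
    recomb_rate: float = 0.02        # per adjacent marker pair within a block
    missing_rate: float = 0.02       # baseline missing-call rate
    high_missing_markers: float = 0.1   # fraction of markers with elevated missing
    high_missing_rate: float = 0.12
    selfing_generations: int = 7
    backcross_fraction: float = 0.15    # fraction of lines from backcrosses


@dataclass
class GEIConfig:
    """True factor-analytic structure: Ge_true = Lambda Lambda' + Psi."""

    k_true: int = 2
    psi: float = 0.04                # specific genetic variance per environment
    # loading r of environment j: intercept + sum_c coef * z(EC_c) + N(0, sd)
    loading_specs: list = field(default_factory=lambda: [
        {"intercept": 0.55, "ecs": {"clay_0_5": 0.20, "TotRain_Sow2Flw": 0.10}, "noise_sd": 0.08},
        {"intercept": 0.0, "ecs": {"Avtemp_He2Flw": -0.30, "AveSR_Juv2He": 0.12}, "noise_sd": 0.08},
    ])
    # main effect of environment j (t/ha): intercept + sum coef * z(EC) + noise
    main_intercept: float = 3.2
    main_ecs: dict = field(default_factory=lambda: {
        "TotRain_Sow2Flw": 0.9, "TotRain_priorSow": 0.35, "Avtemp_He2Flw": -0.45,
        "clay_0_5": 0.30, "TotRain_Flw2Egf": 0.45,
    })
    main_noise_sd: float = 0.35


@dataclass
class DesignConfig:
    check_set_size: int = 8
    entries_bounds: tuple = (10, 475)
    frac_single_rep: float = 0.70    # partial replication mix
    frac_double_rep: float = 0.30
    row_var: float = 0.02
    col_var: float = 0.02
    resid_var: float = 0.08
    ar1_row: float = 0.35
    ar1_col: float = 0.35


@dataclass
class SimulationConfig:
    n_locations: int = 4
    years: list = field(default_factory=lambda: [2020, 2021, 2022])
    latitude_range: tuple = (-36.0, -28.0)
    # per-location rainfall regime; cycled if shorter than n_locations
    rainfall_regimes: list = field(default_factory=lambda: [
        "winter_dominant", "winter_dominant", "winter_dominant", "summer_dominant"])
    sowing_window: tuple = ((5, 10), (6, 10))   # (month, day) bounds for sowing draws
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)
    gei: GEIConfig = field(default_factory=GEIConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    seed: int = 0

    def __post_init__(self):
        if self.gei.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if not all(-60.0 <= la <= 0.0 for la in self.latitude_range):
            raise ConfigurationError("latitudes must be in [-60, 0] (southern hemisphere)")
        for v in (self.design.row_var, self.design.col_var, self.design.resid_var,
                  self.gei.psi, self.weather.noise_sd):
            if v < 0:
                raise ConfigurationError("variances must be >= 0")
        for rho in (self.design.ar1_row, self.design.ar1_col):
            if abs(rho) >= 1:
                raise ConfigurationError("|ar1 correlations| must be < 1")
        if not self.years:
            raise ConfigurationError("years must be non-empty")
        lo, hi = self.design.entries_bounds
        if lo > hi:
            raise ConfigurationError("invalid entries bounds")

    # -- locations -----------------------------------------------------------
    @property
    def locations(self):
        return [f"LOC{i + 1}" for i in range(self.n_locations)]

    def latitude_of(self, location: str) -> float:
        locs = self.locations
        if location in locs:
            i = locs.index(location)
            frac = i / max(1, self.n_locations - 1)
        else:  # extended-grid locations hash (stably) onto the same range
            from .rng import _key_int
            frac = (_key_int(location) % 1000) / 999.0
        lo, hi = self.latitude_range
        return lo + frac * (hi - lo)

    def regime_of(self, location: str) -> str:
        locs = self.locations
        if location in locs:
            return self.rainfall_regimes[locs.index(location) % len(self.rainfall_regimes)]
        # grid locations: northern (latitude closer to 0) -> summer dominant
        return "summer_dominant" if self.latitude_of(location) > -31.0 else "winter_dominant"

    # -- serialisation -------------------------------------------------------
    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        for key, sub in (("weather", WeatherConfig), ("genetics", GeneticsConfig),
                         ("gei", GEIConfig), ("design", DesignConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if isinstance(kwargs.get("design"), DesignConfig) and isinstance(kwargs["design"].entries_bounds, list):
            kwargs["design"].entries_bounds = tuple(kwargs["design"].entries_bounds)
        if "latitude_range" in kwargs:
            kwargs["latitude_range"] = tuple(kwargs["latitude_range"])
        if "sowing_window" in kwargs:
            kwargs["sowing_window"] = tuple(tuple(x) for x in kwargs["sowing_window"])
        return cls(**kwargs)
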