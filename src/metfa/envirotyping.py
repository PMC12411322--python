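"""Envirotyping: growth-stage-anchored weather covariates and soil covariates.

Environments (location-year combinations) are characterised by a vector of
environmental covariates (ECs) derived from daily weather records anchored to
estimated crop growth stages, plus static soil attributes by depth layer.
Growth stages are timed by cumulative thermal time (degree-days) between
cardinal temperatures, following the APSIM wheat convention of a base, optimum
and maximum temperature of 0, 26 and 34 degC.

The seven growth intervals are Sow2Emer, Emer2Juv, Juv2He, He2Flw, Flw2Sgf,
Sgf2Egf and Egf2Mat (sowing, emergence, end of juvenile phase, heading,
flowering, start/end of grain fill, maturity).  Within each interval thirteen
weather ECs are computed (temperature / radiation / day-length / VPD averages,
day counts, rain totals, dry / frost / warm / hot day counts), plus six
multi-interval ECs.  Soil ECs are one value per attribute and depth layer.

Per-environment EC vectors are assembled into the p x w matrix ``W`` used by
the second-stage prediction models, after removal of zero-variance columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CensoredStageError, EmergenceUndefinedError, InputError

__all__ = [
    "WeatherSeries",
    "SoilProfile",
    "GrowthStageDates",
    "ECMatrix",
    "thermal_time",
    "photothermal_quotient",
    "day_length",
    "estimate_growth_stages",
    "interval_ecs",
    "soil_ecs",
    "build_ec_matrix",
    "weather_ecs",
    "HE_THRESHOLDS",
    "SOIL_LAYERS",
    "STAGES",
    "INTERVALS",
]

# Regional cumulative-thermal-time-to-heading defaults (degree-days from sowing).
HE_THRESHOLDS = {"North": 1374.0, "South": 1301.0, "West": 1194.0}

# The six soil depth layers (cm).
SOIL_LAYERS = [(0, 5), (5, 15), (15, 30), (30, 60), (60, 100), (100, 200)]

STAGES = ["Sow", "Emer", "Juv", "He", "Flw", "Sgf", "Egf", "Mat"]
INTERVALS = [
    ("Sow2Emer", "Sow", "Emer"),
    ("Emer2Juv", "Emer", "Juv"),
    ("Juv2He", "Juv", "He"),
    ("He2Flw", "He", "Flw"),
    ("Flw2Sgf", "Flw", "Sgf"),
    ("Sgf2Egf", "Sgf", "Egf"),
    ("Egf2Mat", "Egf", "Mat"),
]

_PAR_FRACTION = 0.47  # solar -> photosynthetically active radiation


@dataclass
class WeatherSeries:
    """Daily weather for one environment (location-year).

    ``records`` columns: date (datetime64[ns], daily, gap-free, increasing),
    rain (mm), tmin (degC), tmax (degC), sr (MJ m-2), vpd (hPa).
    """

    environment: str
    location: str
    latitude: float
    records: pd.DataFrame
    sowing_date: pd.Timestamp | None = None

    def __post_init__(self):
        r = self.records
        required = {"date", "rain", "tmin", "tmax", "sr", "vpd"}
        missing = required - set(r.columns)
        if missing:
            raise InputError(f"weather records missing columns: {sorted(missing)}")
        dates = pd.to_datetime(r["date"])
        diffs = dates.diff().dropna()
        if len(r) > 1 and not (diffs == pd.Timedelta(days=1)).all():
            raise InputError(f"{self.environment}: dates must be daily, gap-free and increasing")
        if (r["tmin"] > r["tmax"]).any():
            raise InputError(f"{self.environment}: tmin > tmax on some days")
        self.records = r.assign(date=dates).reset_index(drop=True)
        if self.sowing_date is not None:
            self.sowing_date = pd.Timestamp(self.sowing_date)


@dataclass
class SoilProfile:
    """Soil attributes by depth layer for one location.

    ``values`` is a DataFrame indexed by attribute name with one column per
    layer labelled ``"<top>_<bottom>"`` in cm.  ``horizon_depths`` holds the
    A/B horizon depths in metres.
    """

    location: str
    values: pd.DataFrame
    horizon_depths: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = [f"{a}_{b}" for a, b in SOIL_LAYERS]
        if list(self.values.columns) != expected:
            raise InputError(f"soil profile must have exactly layers {expected}")


@dataclass
class GrowthStageDates:
    """Estimated dates (and cumulative TT from sowing) of the eight stages."""

    dates: dict
    cum_tt: dict

    def __post_init__(self):
        seq = [pd.Timestamp(self.dates[s]) for s in STAGES]
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise InputError("growth-stage dates must be non-decreasing in stage order")
        tts = [self.cum_tt[s] for s in STAGES]
        if any(b < a - 1e-9 for a, b in zip(tts, tts[1:])):
            raise InputError("cumulative TT must be non-decreasing in stage order")


@dataclass
class ECMatrix:
    """p environments x w covariates, with per-EC provenance (weather|soil)."""

    data: pd.DataFrame
    provenance: pd.Series

    @property
    def environments(self):
        return list(self.data.index)

    @property
    def ec_names(self):
        return list(self.data.columns)

    def subset(self, environments) -> "ECMatrix":
        return ECMatrix(self.data.loc[list(environments)].copy(), self.provenance.copy())


def thermal_time(tmin, tmax):
    """Daily thermal time (degree-days) from min/max temperature.

    TT = T on (0, 26]; (26/8)(34 - T) on (26, 34]; 0 for T <= 0 or T > 34,
    with T the daily mean temperature.  Continuous at both breakpoints and
    bounded by [0, 26].
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise InputError("tmin > tmax")
    t = (tmin + tmax) / 2.0
    tt = np.where(
        (t > 0) & (t <= 26), t,
        np.where((t > 26) & (t <= 34), (26.0 / 8.0) * (34.0 - t), 0.0),
    )
    return tt if tt.ndim else float(tt)


def photothermal_quotient(sr, tmin, tmax):
    """Daily photothermal quotient PQ = (SR * 0.47) / mean temperature.

    Undefined (NaN) on days with zero mean temperature.
    """
    sr = np.asarray(sr, dtype=float)
    t = (np.asarray(tmin, float) + np.asarray(tmax, float)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pq = np.where(t != 0, sr * _PAR_FRACTION / np.where(t != 0, t, 1.0), np.nan)
    return pq if pq.ndim else float(pq)


def day_length(latitude, day_of_year):
    """Daylight hours from the sunrise equation with Spencer's solar declination.

    Valid for |latitude| <= 66.5 (no polar day/night).
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 66.5):
        raise InputError("polar latitudes (|lat| > 66.5) unsupported")
    doy = np.asarray(day_of_year, dtype=float)
    g = 2 * np.pi * (doy - 1.0) / 365.0
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    phi = np.deg2rad(lat)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    hours = 2.0 * np.rad2deg(np.arccos(cos_omega)) / 15.0
    return hours if hours.ndim else float(hours)


def _daily_tt(records: pd.DataFrame) -> np.ndarray:
    return np.asarray(thermal_time(records["tmin"].to_numpy(), records["tmax"].to_numpy()))


def _first_reach(dates, cumsum, threshold, stage):
    idx = np.searchsorted(cumsum, threshold - 1e-12)
    if idx >= len(cumsum):
        raise CensoredStageError(stage)
    return dates[idx]


def estimate_growth_stages(weather: WeatherSeries, sowing_date=None,
                           region_he_threshold: float = HE_THRESHOLDS["South"]) -> GrowthStageDates:
    """Date the eight growth stages from daily weather and a sowing date.

    Emergence is 14 days after sowing when more than 3 mm of rain fell in the
    seven days before sowing, otherwise 14 days after the first post-sowing
    rain day.  Subsequent stages trigger on the first day the running thermal
    time since the anchor stage reaches the threshold: end of juvenile phase
    at 500 TT after emergence; heading at the regional TT-from-sowing
    threshold; flowering, start and end of grain fill each 250 TT after the
    previous stage; maturity 400 TT after end of grain fill.
    """
    sow = pd.Timestamp(sowing_date if sowing_date is not None else weather.sowing_date)
    if pd.isna(sow):
        raise InputError("sowing date required (substitute the dataset median when unknown)")
    rec = weather.records
    dates = rec["date"].to_numpy()
    if sow < rec["date"].iloc[0] or sow > rec["date"].iloc[-1]:
        raise InputError("sowing date outside weather series")

    rain = rec["rain"].to_numpy(float)
    pre_mask = (rec["date"] >= sow - pd.Timedelta(days=7)) & (rec["date"] < sow)
    if rain[pre_mask.to_numpy()].sum() > 3.0:
        emer = sow + pd.Timedelta(days=14)
    else:
        post = (rec["date"] > sow).to_numpy() & (rain > 0)
        if not post.any():
            raise EmergenceUndefinedError(f"{weather.environment}: no rain after sowing")
        emer = pd.Timestamp(dates[np.argmax(post)]) + pd.Timedelta(days=14)
    if emer > rec["date"].iloc[-1]:
        raise CensoredStageError("Emer")

    tt = _daily_tt(rec)

    def cum_from(anchor):
        # running TT over days strictly after the anchor date
        mask = (rec["date"] > anchor).to_numpy()
        return dates[mask], np.cumsum(tt[mask])

    d, c = cum_from(emer)
    juv = pd.Timestamp(_first_reach(d, c, 500.0, "Juv"))
    d, c = cum_from(sow)
    he = pd.Timestamp(_first_reach(d, c, float(region_he_threshold), "He"))
    flw = pd.Timestamp(_first_reach(d, c, float(region_he_threshold) + 250.0, "Flw"))

    d2, c2 = cum_from(flw)
    sgf = pd.Timestamp(_first_reach(d2, c2, 250.0, "Sgf"))
    d2, c2 = cum_from(sgf)
    egf = pd.Timestamp(_first_reach(d2, c2, 250.0, "Egf"))
    d2, c2 = cum_from(egf)
    mat = pd.Timestamp(_first_reach(d2, c2, 400.0, "Mat"))

    # heading must not precede end of juvenile phase; clip forward if the
    # regional threshold is reached first (degenerate warm series)
    if he < juv:
        he = juv
    if flw < he:
        flw = he

    stage_dates = {"Sow": sow, "Emer": emer, "Juv": juv, "He": he,
                   "Flw": flw, "Sgf": sgf, "Egf": egf, "Mat": mat}
    cum_sow = np.cumsum(tt[(rec["date"] > sow).to_numpy()])
    sow_dates = dates[(rec["date"] > sow).to_numpy()]

    def tt_at(dt):
        mask = sow_dates <= np.datetime64(dt)
        return float(cum_sow[mask.sum() - 1]) if mask.any() else 0.0

    cum_tt = {s: tt_at(stage_dates[s]) for s in STAGES}
    return GrowthStageDates(dates=stage_dates, cum_tt=cum_tt)


def _interval_slice(rec: pd.DataFrame, start, end) -> pd.DataFrame:
    # half-open [start, end): consecutive intervals partition the season
    m = (rec["date"] >= start) & (rec["date"] < end)
    return rec.loc[m]


def interval_ecs(weather: WeatherSeries, stages: GrowthStageDates) -> pd.Series:
    """Named weather-EC vector for one environment.

    Thirteen ECs per growth interval plus the six multi-interval ECs.  Empty
    intervals yield NaN averages and zero counts.
    """
    rec = weather.records
    lat = weather.latitude
    out = {}

    def _block(sub: pd.DataFrame, tag: str):
        n = len(sub)
        if n == 0:
            for name in ("Avtemp", "Avmintemp", "Avmaxtemp", "AveDL", "AveSR", "AveVPD", "AvePQ"):
                out[f"{name}_{tag}"] = np.nan
            for name in ("Ndays", "TotRain", "Ndd", "Ndays<0", "Ndays>26", "Ndays>34"):
                out[f"{name}_{tag}"] = 0.0
            return
        tmin = sub["tmin"].to_numpy(float)
        tmax = sub["tmax"].to_numpy(float)
        rain = sub["rain"].to_numpy(float)
        doy = sub["date"].dt.dayofyear.to_numpy()
        out[f"Avtemp_{tag}"] = float(np.mean((tmin + tmax) / 2))
        out[f"Avmintemp_{tag}"] = float(np.mean(tmin))
        out[f"Avmaxtemp_{tag}"] = float(np.mean(tmax))
        out[f"AveDL_{tag}"] = float(np.mean(day_length(lat, doy)))
        out[f"AveSR_{tag}"] = float(np.mean(sub["sr"].to_numpy(float)))
        out[f"AveVPD_{tag}"] = float(np.mean(sub["vpd"].to_numpy(float)))
        pq = photothermal_quotient(sub["sr"].to_numpy(float), tmin, tmax)
        out[f"AvePQ_{tag}"] = float(np.nanmean(pq)) if np.isfinite(pq).any() else np.nan
        out[f"Ndays_{tag}"] = float(n)
        out[f"TotRain_{tag}"] = float(rain.sum())
        out[f"Ndd_{tag}"] = float((rain == 0).sum())
        out[f"Ndays<0_{tag}"] = float((tmin < 0).sum())
        out[f"Ndays>26_{tag}"] = float((tmax > 26).sum())
        out[f"Ndays>34_{tag}"] = float((tmax > 34).sum())

    for tag, s0, s1 in INTERVALS:
        _block(_interval_slice(rec, stages.dates[s0], stages.dates[s1]), tag)

    sow, flw, egf = stages.dates["Sow"], stages.dates["Flw"], stages.dates["Egf"]
    sub = _interval_slice(rec, sow, flw)
    out["TotRain_Sow2Flw"] = float(sub["rain"].sum())
    out["Ndays_Sow2Flw"] = float(len(sub))
    sub = _interval_slice(rec, flw, egf)
    out["TotRain_Flw2Egf"] = float(sub["rain"].sum())
    out["Ndays_Flw2Egf"] = float(len(sub))
    jan1 = pd.Timestamp(year=sow.year, month=1, day=1)
    out["TotRain_priorSow"] = float(_interval_slice(rec, jan1, sow)["rain"].sum())
    near_flw = rec[(rec["date"] >= flw - pd.Timedelta(days=7)) & (rec["date"] <= flw + pd.Timedelta(days=7))]
    out["Mintemp<0_Flw"] = float((near_flw["tmin"] < 0).sum())

    return pd.Series(out, dtype=float)


def weather_ecs(weather: WeatherSeries, sowing_date=None,
                region_he_threshold: float = HE_THRESHOLDS["South"]) -> pd.Series:
    """Convenience: growth stages + interval ECs in one call."""
    stages = estimate_growth_stages(weather, sowing_date, region_he_threshold)
    return interval_ecs(weather, stages)


def soil_ecs(profile: SoilProfile) -> pd.Series:
    """Named soil-EC vector: one EC per (attribute, layer) plus horizon depths.

    Missing attribute cells are absent from the vector (not zero).
    """
    out = {}
    for attr, row in profile.values.iterrows():
        for layer, val in row.items():
            if pd.notna(val):
                out[f"{attr}_{layer}"] = float(val)
    for hz, depth in profile.horizon_depths.items():
        out[f"horizon_{hz}_depth"] = float(depth)
    return pd.Series(out, dtype=float)


def build_ec_matrix(vectors: dict, soil_names=None, zero_var_tol: float = 1e-12) -> ECMatrix:
    """Assemble per-environment EC vectors into the p x w matrix W.

    Zero-variance columns (population variance < `zero_var_tol` after scaling
    columns to unit max magnitude) are dropped; remaining missing cells are
    imputed with the column mean.  Environments with all-missing vectors are
    rejected.
    """
    if len(vectors) < 2:
        raise InputError("need at least 2 environments to define EC variance")
    df = pd.DataFrame({env: v for env, v in vectors.items()}).T
    df.index.name = "environment"
    bad = df.index[df.isna().all(axis=1)]
    if len(bad):
        raise InputError(f"environments with all-missing ECs: {list(bad)}")

    scale = df.abs().max(axis=0).replace(0, 1.0)
    scaled = df / scale
    variances = scaled.var(axis=0, ddof=0)
    keep = variances.index[(variances > zero_var_tol) & variances.notna()]
    df = df[keep]
    df = df.fillna(df.mean(axis=0))

    soil_names = set(soil_names or ())
    prov = pd.Series(
        ["soil" if c in soil_names or c.startswith("horizon_") else "weather" for c in df.columns],
        index=df.columns,
    )
    return ECMatrix(data=df, provenance=prov)
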