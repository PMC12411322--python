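"""Synthetic southern-hemisphere daily weather.

Temperature follows a sinusoidal annual cycle (summer peak in mid-January)
plus AR(1) daily noise; rainfall is a seasonally weighted Bernoulli-Gamma
process with winter-dominant or summer-dominant seasonality; solar radiation
tracks the temperature season; vapour-pressure deficit increases with daily
maximum temperature.  This is the minimal weather model that reproduces the
rain/temperature/radiation structure the envirotyping stage needs.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..envirotyping import WeatherSeries
from ..errors import ConfigurationError
from ..rng import stream

__all__ = ["simulate_weather", "sowing_date_for"]

_SUMMER_PEAK_DOY = 15.0   # mid-January (southern hemisphere summer)
_WINTER_PEAK_DOY = 196.0  # mid-July


def _annual_cycle(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.0)


def sowing_date_for(config: SimulationConfig, location: str, year: int) -> pd.Timestamp:
    """Seeded sowing date within the configured sowing window."""
    (m0, d0), (m1, d1) = config.sowing_window
    lo = pd.Timestamp(year=year, month=m0, day=d0)
    hi = pd.Timestamp(year=year, month=m1, day=d1)
    rng = stream(config.seed, "sowing", location, year)
    offset = int(rng.integers(0, max(1, (hi - lo).days + 1)))
    return lo + pd.Timedelta(days=offset)


def simulate_weather(config: SimulationConfig, location: str, year: int,
                     with_sowing: bool = True) -> WeatherSeries:
    """Daily weather for one location-year; deterministic for a fixed seed."""
    lat = config.latitude_of(location)
    if not (-60.0 <= lat <= 0.0):
        raise ConfigurationError(f"latitude {lat} outside [-60, 0]")
    ndays = 366 if calendar.isleap(year) else 365
    if ndays <= 0:
        raise ConfigurationError("empty year")
    # cover the full season: the calendar year plus the following Jan-Apr so
    # late grain fill and maturity are never censored by the year boundary
    ndays += 120
    wc = config.weather
    rng = stream(config.seed, "weather", location, year)

    doy = np.arange(1, ndays + 1, dtype=float)
    mean_loc = wc.mean_temp + wc.lat_gradient * (lat - np.mean(config.latitude_range))
    # the annual cycle is written on tmax: with zero noise the peak-day tmax
    # is exactly mean + amplitude
    centre = mean_loc + wc.amplitude * _annual_cycle(doy, _SUMMER_PEAK_DOY)

    # AR(1) noise shared by tmin/tmax plus independent day-level jitter,
    # both scaled by the configured noise sd
    eps = np.empty(ndays)
    innov = rng.normal(0.0, 1.0, ndays)
    eps[0] = innov[0]
    for d in range(1, ndays):
        eps[d] = wc.noise_ar1 * eps[d - 1] + np.sqrt(1 - wc.noise_ar1**2) * innov[d]
    noise = wc.noise_sd * eps
    jit = np.abs(rng.normal(0.0, 0.25 * wc.noise_sd, (2, ndays))) if wc.noise_sd > 0 else np.zeros((2, ndays))
    tmax = centre + noise + jit[0]
    tmin = tmax - wc.diurnal_range - jit[1]

    # seasonal Bernoulli-Gamma rainfall
    regime = config.regime_of(location)
    peak = _WINTER_PEAK_DOY if regime == "winter_dominant" else _SUMMER_PEAK_DOY
    weight = 1.0 + wc.rain_seasonality * _annual_cycle(doy, peak)
    p_wet = np.clip(wc.wet_day_prob * weight, 0.0, 0.95)
    wet = rng.random(ndays) < p_wet
    mean_amount = config.weather.annual_rain_mm / max(p_wet.sum(), 1.0)
    amounts = rng.gamma(wc.rain_shape, mean_amount * weight / wc.rain_shape, ndays)
    rain = np.where(wet, amounts, 0.0)

    sr = np.clip(
        18.0 + 8.0 * _annual_cycle(doy, _SUMMER_PEAK_DOY) + rng.normal(0, 2.0, ndays),
        1.0, None)
    vpd = np.clip(1.5 + 0.55 * (tmax - 10.0) + rng.normal(0, 1.0, ndays), 0.0, None)

    records = pd.DataFrame({
        "date": pd.date_range(f"{year}-01-01", periods=ndays, freq="D"),
        "rain": rain, "tmin": tmin, "tmax": tmax, "sr": sr, "vpd": vpd,
    })
    sow = sowing_date_for(config, location, year) if with_sowing else None
    return WeatherSeries(environment=f"{location}_{year}", location=location,
                         latitude=lat, records=records, sowing_date=sow)
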