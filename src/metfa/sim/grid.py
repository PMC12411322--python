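"""Extended environment grids for prediction beyond the trial network.

Grid locations stand in for the cropping-area mask of a national wheat belt:
each grid point gets synthetic weather and soil from the same generators as
the training locations (a grid id equal to a training location id reproduces
the training environment exactly), and a complete EC vector with the default
sowing date of 24 May.
"""

from __future__ import annotations

import pandas as pd

from ..config import SimulationConfig
from ..envirotyping import ECMatrix, HE_THRESHOLDS, build_ec_matrix, soil_ecs, weather_ecs
from ..errors import ConfigurationError
from .met import region_of
from .soil import simulate_soil
from .weather import simulate_weather

__all__ = ["simulate_extended_grid", "extended_ec_matrix", "DEFAULT_GRID_SOWING"]

DEFAULT_GRID_SOWING = (5, 24)  # 24 May


def simulate_extended_grid(config: SimulationConfig, n_grid_locations: int, years,
                           location_ids=None):
    """Weather and soil for a grid of locations x years.

    Returns a list of (WeatherSeries, SoilProfile) pairs, one per grid
    environment, with sowing date fixed to 24 May.
    """
    if n_grid_locations < 1:
        raise ConfigurationError("n_grid_locations must be >= 1")
    if location_ids is None:
        location_ids = [f"GRID{i + 1:03d}" for i in range(n_grid_locations)]
    out = []
    for loc in location_ids:
        profile = simulate_soil(config, loc)
        for year in years:
            weather = simulate_weather(config, loc, year, with_sowing=False)
            weather.sowing_date = pd.Timestamp(year=int(year), month=DEFAULT_GRID_SOWING[0],
                                               day=DEFAULT_GRID_SOWING[1])
            out.append((weather, profile))
    return out


def extended_ec_matrix(config: SimulationConfig, grid, training_ec: ECMatrix) -> ECMatrix:
    """EC matrix for extended environments on the training EC name universe.

    Columns are aligned to the training matrix (same names, same order);
    missing cells are filled with the training column mean.
    """
    vectors, soil_names = {}, set()
    for weather, profile in grid:
        svec = soil_ecs(profile)
        soil_names |= set(svec.index)
        wvec = weather_ecs(weather,
                           region_he_threshold=HE_THRESHOLDS[region_of(config, weather.location)])
        vectors[weather.environment] = pd.concat([wvec, svec])
    df = pd.DataFrame({env: v for env, v in vectors.items()}).T
    df = df.reindex(columns=training_ec.data.columns)
    df = df.fillna(training_ec.data.mean(axis=0))
    return ECMatrix(data=df, provenance=training_ec.provenance.copy())
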