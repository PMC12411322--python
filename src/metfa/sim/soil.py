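"""Synthetic layered soil profiles.

Each location draws a "heaviness" index in [0, 1] controlling the
clay/silt/sand balance (heavier soils: more clay, higher water capacity and
cation exchange) and a fertility index controlling carbon/nutrient levels.
Fifteen attributes are generated for the six standard depth layers; texture
percentages close to 100 per layer.  A/B horizon depths use fixed defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..envirotyping import SOIL_LAYERS, SoilProfile
from ..rng import stream

__all__ = ["simulate_soil", "SOIL_ATTRIBUTES"]

SOIL_ATTRIBUTES = [
    "clay", "silt", "sand", "awc", "bulk_density", "cec", "organic_carbon",
    "particulate_oc", "coarse_fragments", "ph_water", "total_n", "total_p",
    "available_p", "dul", "dll",
]

_LAYER_LABELS = [f"{a}_{b}" for a, b in SOIL_LAYERS]
_HORIZON_DEPTHS = {"A": 0.3, "B": 1.2}  # m; fixed across locations


def simulate_soil(config: SimulationConfig, location: str,
                  heaviness: float | None = None) -> SoilProfile:
    """Soil profile for one location; heavier presets via ``heaviness``."""
    rng = stream(config.seed, "soil", location)
    t = float(rng.uniform(0.1, 0.9)) if heaviness is None else float(np.clip(heaviness, 0, 1))
    fert = float(rng.uniform(0.2, 0.9))
    depth_mid = np.array([(a + b) / 2.0 for a, b in SOIL_LAYERS]) / 200.0  # 0..1

    vals = {}
    jitter = rng.normal(0, 1.0, (len(SOIL_ATTRIBUTES), len(SOIL_LAYERS)))
    clay = np.clip(12.0 + 38.0 * t + 14.0 * depth_mid + 2.0 * jitter[0], 2.0, 72.0)
    sand = np.clip(78.0 - 52.0 * t - 12.0 * depth_mid + 2.0 * jitter[2], 5.0, 92.0)
    # closure: silt absorbs the remainder, then renormalise to exactly 100
    silt = np.clip(100.0 - clay - sand, 2.0, None)
    total = clay + silt + sand
    clay, silt, sand = 100 * clay / total, 100 * silt / total, 100 * sand / total
    vals["clay"], vals["silt"], vals["sand"] = clay, silt, sand

    vals["awc"] = np.clip(7.0 + 9.0 * t - 2.0 * depth_mid + 0.5 * jitter[3], 2.0, 25.0)
    vals["bulk_density"] = np.clip(1.25 + 0.25 * depth_mid + 0.1 * (1 - t) + 0.03 * jitter[4], 0.9, 1.9)
    vals["cec"] = np.clip(4.0 + 22.0 * t + 3.0 * depth_mid + 1.0 * jitter[5], 1.0, 40.0)
    oc_surface = 0.4 + 1.6 * fert
    vals["organic_carbon"] = np.clip(oc_surface * np.exp(-3.0 * depth_mid) + 0.05 * jitter[6], 0.01, 4.0)
    vals["particulate_oc"] = np.clip(0.4 * vals["organic_carbon"] + 0.02 * jitter[7], 0.005, 2.0)
    vals["coarse_fragments"] = np.clip(3.0 + 10.0 * (1 - t) * depth_mid + 1.0 * jitter[8], 0.0, 40.0)
    vals["ph_water"] = np.clip(5.6 + 1.8 * t + 1.2 * depth_mid + 0.15 * jitter[9], 3.0, 11.0)
    vals["total_n"] = np.clip(0.02 + 0.13 * fert * np.exp(-2.5 * depth_mid) + 0.004 * jitter[10], 0.001, 0.5)
    vals["total_p"] = np.clip(0.01 + 0.05 * fert * np.exp(-2.0 * depth_mid) + 0.002 * jitter[11], 0.001, 0.2)
    vals["available_p"] = np.clip(8.0 + 30.0 * fert * np.exp(-3.0 * depth_mid) + 1.5 * jitter[12], 0.5, 80.0)
    vals["dul"] = np.clip(14.0 + 18.0 * t + 1.0 * jitter[13], 5.0, 45.0)
    vals["dll"] = np.clip(vals["dul"] - vals["awc"], 2.0, None)

    table = pd.DataFrame(
        {lab: [vals[a][i] for a in SOIL_ATTRIBUTES] for i, lab in enumerate(_LAYER_LABELS)},
        index=SOIL_ATTRIBUTES,
    )
    return SoilProfile(location=location, values=table, horizon_depths=dict(_HORIZON_DEPTHS))
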