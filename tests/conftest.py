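import numpy as np
import pandas as pd
import pytest

from metfa.config import GeneticsConfig, SimulationConfig
from metfa.envirotyping import WeatherSeries


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def clean_genetics_config():
    """Panel without missing calls, for masking experiments."""
    return SimulationConfig(
        seed=11,
        genetics=GeneticsConfig(missing_rate=0.0, high_missing_markers=0.0,
                                n_lines=80, n_markers=60))


def constant_weather(tmean=20.0, ndays=400, rain_pattern=None, latitude=-33.0,
                     start="2021-01-01", environment="TOY_2021"):
    """Deterministic weather series: constant temperature, scripted rain."""
    dates = pd.date_range(start, periods=ndays, freq="D")
    rain = np.zeros(ndays) if rain_pattern is None else np.asarray(rain_pattern, float)
    rec = pd.DataFrame({
        "date": dates,
        "rain": rain,
        "tmin": np.full(ndays, tmean - 5.0),
        "tmax": np.full(ndays, tmean + 5.0),
        "sr": np.full(ndays, 18.0),
        "vpd": np.full(ndays, 8.0),
    })
    return WeatherSeries(environment=environment, location="TOY", latitude=latitude,
                         records=rec)


@pytest.fixture
def toy_weather():
    return constant_weather


def balanced_met(seed=0, n=30, p=4, k=1, reps=2, psi=0.1, resid=0.2,
                 lam_scale=(0.4, 0.9)):
    """Complete-design MET with known FA structure and a dense kernel."""
    rng = np.random.default_rng(seed)
    ids = [f"g{i:03d}" for i in range(n)]
    envs = [f"e{j:02d}" for j in range(p)]
    A = rng.normal(size=(n, max(2 * n, 40)))
    Gn = A @ A.T / A.shape[1] + 0.3 * np.eye(n)
    Gdf = pd.DataFrame(Gn, index=ids, columns=ids)
    # well-separated structure: a dominant positive first factor, weaker
    # sign-varying higher factors, so the principal-component rotation of the
    # truth is stable and factor-wise comparisons are meaningful
    lam = np.column_stack([rng.uniform(*lam_scale, p)] + [
        0.6 * rng.uniform(*lam_scale, p) * rng.choice([-1, 1], p)
        for _ in range(k - 1)])
    Ge = lam @ lam.T + psi * np.eye(p)
    L = np.linalg.cholesky(Gn)
    w_ge, V_ge = np.linalg.eigh(Ge)
    Ge_half = V_ge @ np.diag(np.sqrt(np.clip(w_ge, 0, None))) @ V_ge.T
    U = (L @ rng.normal(size=(n, p))) @ Ge_half
    tau = rng.normal(3.0, 1.0, p)
    rows = []
    for j, e in enumerate(envs):
        slot = 0
        for i, g in enumerate(ids):
            for _ in range(reps):
                rows.append((e, 2020 + j, "L", g, slot // 12 + 1, slot % 12 + 1,
                             tau[j] + U[i, j] + rng.normal(0, np.sqrt(resid))))
                slot += 1
    plots = pd.DataFrame(rows, columns=["environment", "year", "location",
                                        "genotype", "row", "col", "yield"])
    return {"plots": plots, "kernel": Gdf, "lam": lam, "Ge": Ge, "tau": tau,
            "U": U, "envs": envs, "ids": ids, "psi": np.full(p, psi)}
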