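"""Delimited-text readers and writers for the pipeline artefacts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .envirotyping import ECMatrix, SoilProfile, WeatherSeries


def write_weather(weather: WeatherSeries, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{weather.environment}.csv"
    weather.records.to_csv(path, index=False)
    meta = {"environment": weather.environment, "location": weather.location,
            "latitude": weather.latitude,
            "sowing_date": str(weather.sowing_date.date()) if weather.sowing_date is not None else None}
    (directory / f"{weather.environment}.meta.json").write_text(json.dumps(meta))
    return path


def read_weather(path) -> WeatherSeries:
    path = Path(path)
    records = pd.read_csv(path, parse_dates=["date"])
    meta = json.loads((path.parent / f"{path.stem}.meta.json").read_text())
    sow = meta.get("sowing_date")
    return WeatherSeries(environment=meta["environment"], location=meta["location"],
                         latitude=float(meta["latitude"]), records=records,
                         sowing_date=pd.Timestamp(sow) if sow else None)


def write_soil(profile: SoilProfile, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{profile.location}.soil.csv"
    profile.values.to_csv(path)
    (directory / f"{profile.location}.soil.meta.json").write_text(
        json.dumps({"location": profile.location, "horizon_depths": profile.horizon_depths}))
    return path


def read_soil(path) -> SoilProfile:
    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    meta = json.loads((path.parent / f"{path.stem}.meta.json").read_text())
    return SoilProfile(location=meta["location"], values=values,
                       horizon_depths=meta.get("horizon_depths", {}))


def write_ec_matrix(ec: ECMatrix, path, meta_path=None):
    ec.data.to_csv(path)
    if meta_path is not None and ec.provenance is not None:
        ec.provenance.rename("provenance").to_csv(meta_path)


def read_ec_matrix(path, meta_path=None) -> ECMatrix:
    data = pd.read_csv(path, index_col=0)
    prov = None
    if meta_path is not None and Path(meta_path).exists():
        prov = pd.read_csv(meta_path, index_col=0)["provenance"]
    return ECMatrix(data=data, provenance=prov)


def write_matrix(df: pd.DataFrame, path):
    df.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_fit(fit, directory):
    """Serialise an FA model fit as a directory of delimited tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fit.main_effects.rename("main_effect").to_csv(directory / "main_effects.csv")
    fit.resid_var.rename("resid_var").to_csv(directory / "resid_var.csv")
    if fit.lam is not None:
        fit.lam.to_csv(directory / "loadings.csv")
    if fit.psi is not None:
        fit.psi.rename("psi").to_csv(directory / "psi.csv")
    if fit.scores is not None:
        fit.scores.to_csv(directory / "scores.csv")
    fit.env_effects.to_csv(directory / "env_effects.csv")
    manifest = {
        "model": fit.model, "kernel": fit.kernel_kind, "loglik": fit.loglik,
        "aic": fit.aic, "bic": fit.bic, "n_vparams": fit.n_vparams,
        "converged": fit.converged, "rotated": fit.rotated,
        "environments": fit.environments,
        "dropped_genotypes": fit.dropped_genotypes,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
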