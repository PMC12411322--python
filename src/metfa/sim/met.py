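"""Plot-level MET simulation from a known factor-analytic GEI structure.

Environmental main effects and true factor loadings are functions of named
environmental covariates (standardised across the simulated environments)
plus noise; genetic values have covariance (Lambda Lambda' + Psi) x Gn; the
trial design is partially replicated with year-specific cohorts plus
multi-year checks; plot errors include row/column effects and an ar1 x ar1
correlated residual field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..envirotyping import ECMatrix, HE_THRESHOLDS, build_ec_matrix, soil_ecs, weather_ecs
from ..errors import ConfigurationError
from ..genetics import RelationshipMatrix
from ..rng import stream
from .genotypes import check_ids
from .soil import simulate_soil
from .weather import simulate_weather

__all__ = ["TrueParams", "simulate_met", "build_training_ecs", "region_of"]


def region_of(config: SimulationConfig, location: str) -> str:
    """Growing-region label (sets the thermal-time-to-heading threshold)."""
    return "North" if config.regime_of(location) == "summer_dominant" else "South"


@dataclass
class TrueParams:
    """Ground truth of the generative model."""

    lambda_true: pd.DataFrame        # p x k loadings
    d_true: np.ndarray               # k x k (identity scale held in loadings)
    psi_true: pd.Series              # p specific variances
    scores_true: pd.DataFrame        # n x k genotype scores
    main_effects: pd.Series          # p environment main effects
    main_coefficients: dict          # EC name -> coefficient (standardised scale)
    genetic_values: pd.DataFrame     # n x p noise-free genetic values

    @property
    def ge_true(self) -> pd.DataFrame:
        lam = self.lambda_true.to_numpy()
        ge = lam @ self.d_true @ lam.T + np.diag(self.psi_true.to_numpy())
        return pd.DataFrame(ge, index=self.lambda_true.index, columns=self.lambda_true.index)


def build_training_ecs(config: SimulationConfig) -> ECMatrix:
    """Derive the training EC matrix for every simulated environment."""
    vectors, soil_names = {}, set()
    for loc in config.locations:
        profile = simulate_soil(config, loc)
        svec = soil_ecs(profile)
        soil_names |= set(svec.index)
        for year in config.years:
            weather = simulate_weather(config, loc, year)
            wvec = weather_ecs(weather, region_he_threshold=HE_THRESHOLDS[region_of(config, loc)])
            vectors[f"{loc}_{year}"] = pd.concat([wvec, svec])
    return build_ec_matrix(vectors, soil_names=soil_names)


def _standardise(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    return (col - col.mean()) / (sd if sd > 0 else 1.0)


def _ec_driver(ec: ECMatrix, names_coefs: dict, envs) -> np.ndarray:
    out = np.zeros(len(envs))
    for name, coef in names_coefs.items():
        if name not in ec.data.columns:
            raise ConfigurationError(f"EC '{name}' in effect specification absent from EC matrix")
        out += coef * _standardise(ec.data.loc[envs, name].to_numpy(float))
    return out


def true_structure(config: SimulationConfig, ec: ECMatrix):
    """True loadings and main effects as configured functions of the ECs."""
    envs = ec.environments
    p, k = len(envs), config.gei.k_true
    specs = config.gei.loading_specs
    if len(specs) < k:
        raise ConfigurationError("need one loading spec per true factor")
    rng = stream(config.seed, "truth")
    lam = np.zeros((p, k))
    for r in range(k):
        spec = specs[r]
        lam[:, r] = (spec.get("intercept", 0.0) + _ec_driver(ec, spec.get("ecs", {}), envs)
                     + rng.normal(0, spec.get("noise_sd", 0.0), p))
    main = (config.gei.main_intercept + _ec_driver(ec, config.gei.main_ecs, envs)
            + rng.normal(0, config.gei.main_noise_sd, p))
    lam_df = pd.DataFrame(lam, index=envs, columns=[f"fac{r + 1}" for r in range(k)])
    psi = pd.Series(config.gei.psi, index=envs)
    return lam_df, psi, pd.Series(main, index=envs)


def simulate_met(config: SimulationConfig, ec_matrix: ECMatrix,
                 relationship: RelationshipMatrix):
    """Simulate plot-level yields; returns (plot table, TrueParams).

    The plot table has columns environment, year, location, genotype, row,
    col, yield (t/ha).
    """
    envs = ec_matrix.environments
    ids = relationship.ids
    n, p, k = len(ids), len(envs), config.gei.k_true
    lam_df, psi, main = true_structure(config, ec_matrix)

    # genetic values: scores ~ N(0, I_k x Gn); specific ~ N(0, psi_j Gn)
    rng = stream(config.seed, "genetic_values")
    Gn = relationship.values.to_numpy(float)
    w, V = np.linalg.eigh((Gn + Gn.T) / 2.0)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    scores = L @ rng.normal(0, 1, (n, k))
    specific = L @ rng.normal(0, 1, (n, p)) * np.sqrt(psi.to_numpy())[None, :]
    U = scores @ lam_df.to_numpy().T + specific

    truth = TrueParams(
        lambda_true=lam_df, d_true=np.eye(k), psi_true=psi,
        scores_true=pd.DataFrame(scores, index=ids, columns=lam_df.columns),
        main_effects=main, main_coefficients=dict(config.gei.main_ecs),
        genetic_values=pd.DataFrame(U, index=ids, columns=envs),
    )

    checks = [c for c in check_ids(config) if c in ids]
    cohorts = {y: [g for g in ids if g.startswith(f"Y{y}_")] for y in config.years}
    dc = config.design
    lo_bound, hi_bound = dc.entries_bounds
    rows = []
    for j, env in enumerate(envs):
        loc, year = env.rsplit("_", 1)
        erng = stream(config.seed, "design", env)
        entries = checks + cohorts.get(int(year), [])
        if not (lo_bound <= len(entries) <= hi_bound):
            raise ConfigurationError(
                f"{env}: {len(entries)} entries outside configured bounds {dc.entries_bounds}")
        # partial replication: the configured single/double mix applies to all
        # entries (the multi-year connectivity comes from the check set)
        reps = [2 if erng.random() < dc.frac_double_rep else 1 for _ in entries]
        nplots = int(np.sum(reps))
        ncol = int(np.ceil(np.sqrt(nplots)))
        nrow = int(np.ceil(nplots / ncol))
        cells = [(r, c) for r in range(1, nrow + 1) for c in range(1, ncol + 1)][:nplots]
        order = erng.permutation(nplots)

        row_eff = erng.normal(0, np.sqrt(dc.row_var), nrow)
        col_eff = erng.normal(0, np.sqrt(dc.col_var), ncol)
        if dc.resid_var > 0:
            Kr = _ar1_corr(nrow, dc.ar1_row)
            Kc = _ar1_corr(ncol, dc.ar1_col)
            field = (np.linalg.cholesky(Kr) @ erng.normal(0, 1, (nrow, ncol))
                     @ np.linalg.cholesky(Kc).T) * np.sqrt(dc.resid_var)
        else:
            field = np.zeros((nrow, ncol))

        plot_entries = [g for g, r in zip(entries, reps) for _ in range(r)]
        for slot, g in enumerate(plot_entries):
            r, c = cells[order[slot]]
            gi = ids.index(g)
            y = main[env] + U[gi, j] + row_eff[r - 1] + col_eff[c - 1] + field[r - 1, c - 1]
            rows.append((env, int(year), loc, g, r, c, y))

    plots = pd.DataFrame(rows, columns=["environment", "year", "location",
                                        "genotype", "row", "col", "yield"])
    return plots, truth


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])
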