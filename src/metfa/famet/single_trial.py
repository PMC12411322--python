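"""Single-trial spatial mixed models with AIC structure selection.

For each trial the model y = mu + Z_g u_g + [Z_row u_r] + [Z_col u_c] + eps
is fitted by REML for every candidate structure in a grid of optional random
row/column effects crossed with separable residual correlation (independent,
first- or second-order autoregressive in each of the row and column
directions).  The converged candidate with the lowest AIC is selected.
Genotype reliabilities r_i = 1 - PEV_i / sigma2_G feed the environment
filter used before multi-environment modelling.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import optimize

from ..errors import FitError, InputError
from .types import SingleTrialFit, TrialStructure

__all__ = ["candidate_structures", "fit_single_trial", "reliability_filter",
           "residual_correlation"]

_LOG2PI = np.log(2.0 * np.pi)


def candidate_structures(include_ar2: bool = False):
    """Default candidate grid: {+-row} x {+-col} x {id, ar1[, ar2]}^2."""
    resid = ["id", "ar1"] + (["ar2"] if include_ar2 else [])
    return [TrialStructure(r, c, rr, rc)
            for r, c, rr, rc in itertools.product([False, True], [False, True], resid, resid)]


def _ar_corr_vec(max_lag: int, kind: str, params) -> np.ndarray:
    """Autocorrelation by lag 0..max_lag for id/ar1/ar2 processes."""
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    if kind == "id" or max_lag == 0:
        return rho
    if kind == "ar1":
        rho[1:] = params[0] ** np.arange(1, max_lag + 1)
        return rho
    # ar2 via partial autocorrelations (pi1, pi2): phi2 = pi2, phi1 = pi1(1-pi2)
    pi1, pi2 = params
    phi1, phi2 = pi1 * (1 - pi2), pi2
    rho[1] = phi1 / (1 - phi2)
    for h in range(2, max_lag + 1):
        rho[h] = phi1 * rho[h - 1] + phi2 * rho[h - 2]
    return rho


def residual_correlation(rows, cols, structure: TrialStructure, params: dict) -> np.ndarray:
    """Separable residual correlation K over the observed plot positions."""
    rows = np.asarray(rows, int)
    cols = np.asarray(cols, int)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    kr = _ar_corr_vec(dr.max(), structure.resid_row,
                      params.get("row_params", ()))[dr]
    kc = _ar_corr_vec(dc.max(), structure.resid_col,
                      params.get("col_params", ()))[dc]
    return kr * kc


def _n_corr_params(kind: str) -> int:
    return {"id": 0, "ar1": 1, "ar2": 2}[kind]


class _TrialData:
    def __init__(self, plots: pd.DataFrame):
        required = {"genotype", "row", "col", "yield"}
        if not required <= set(plots.columns):
            raise InputError(f"plot table needs columns {sorted(required)}")
        if plots.duplicated(["row", "col"]).any():
            raise InputError("duplicate plot coordinates in trial")
        self.y = plots["yield"].to_numpy(float)
        self.genos = pd.Categorical(plots["genotype"])
        if len(self.genos.categories) < 2:
            raise InputError("need >= 2 genotypes")
        self.rows = plots["row"].to_numpy(int)
        self.cols = plots["col"].to_numpy(int)
        self.n = len(self.y)
        self.Zg = np.eye(len(self.genos.categories))[self.genos.codes]
        self.Zr = pd.get_dummies(self.rows).to_numpy(float)
        self.Zc = pd.get_dummies(self.cols).to_numpy(float)
        self.GG = self.Zg @ self.Zg.T
        self.RR = self.Zr @ self.Zr.T
        self.CC = self.Zc @ self.Zc.T


def _unpack(theta, structure: TrialStructure):
    i = 0
    sg2 = np.exp(theta[i]); i += 1
    sr2 = sc2 = 0.0
    if structure.row_effect:
        sr2 = np.exp(theta[i]); i += 1
    if structure.col_effect:
        sc2 = np.exp(theta[i]); i += 1
    se2 = np.exp(theta[i]); i += 1
    nr = _n_corr_params(structure.resid_row)
    row_p = tuple(np.tanh(theta[i:i + nr])); i += nr
    nc = _n_corr_params(structure.resid_col)
    col_p = tuple(np.tanh(theta[i:i + nc])); i += nc
    return sg2, sr2, sc2, se2, {"row_params": row_p, "col_params": col_p}


def _reml_ll(theta, data: _TrialData, structure: TrialStructure):
    sg2, sr2, sc2, se2, cpar = _unpack(theta, structure)
    K = residual_correlation(data.rows, data.cols, structure, cpar)
    V = sg2 * data.GG + se2 * K
    if structure.row_effect:
        V = V + sr2 * data.RR
    if structure.col_effect:
        V = V + sc2 * data.CC
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V, data.y)
    Vi_1 = np.linalg.solve(V, np.ones(data.n))
    xvx = np.ones(data.n) @ Vi_1
    mu = (np.ones(data.n) @ Vi_y) / xvx
    resid = data.y - mu
    ypy = resid @ np.linalg.solve(V, resid)
    ll = -0.5 * ((data.n - 1) * _LOG2PI + logdet + np.log(xvx) + ypy)
    return ll, (V, mu, sg2)


def _fit_structure(data: _TrialData, structure: TrialStructure):
    var_y = max(np.var(data.y), 1e-6)
    theta0 = [np.log(var_y / 2)]
    if structure.row_effect:
        theta0.append(np.log(var_y / 10))
    if structure.col_effect:
        theta0.append(np.log(var_y / 10))
    theta0.append(np.log(var_y / 2))
    theta0 += [np.arctanh(0.3)] * (_n_corr_params(structure.resid_row)
                                   + _n_corr_params(structure.resid_col))
    theta0 = np.array(theta0)

    def nll(th):
        ll, _ = _reml_ll(th, data, structure)
        return 1e10 if not np.isfinite(ll) else -ll

    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": 200, "ftol": 1e-10})
    if not np.isfinite(res.fun):
        return None
    ll, aux = _reml_ll(res.x, data, structure)
    if aux is None:
        return None
    return res.x, ll, aux


def fit_single_trial(plots: pd.DataFrame, structures=None,
                     include_ar2: bool = False, environment: str | None = None) -> SingleTrialFit:
    """Fit all candidate structures for one trial; return the lowest-AIC fit."""
    data = _TrialData(plots)
    if environment is None:
        environment = str(plots["environment"].iloc[0]) if "environment" in plots else "trial"
    env = environment
    if structures is None:
        structures = candidate_structures(include_ar2)
    # structurally unidentifiable cells: effects/correlation along a direction
    # with a single level
    nr_levels, nc_levels = data.Zr.shape[1], data.Zc.shape[1]
    structures = [s for s in structures
                  if not ((s.row_effect or s.resid_row != "id") and nr_levels < 2)
                  and not ((s.col_effect or s.resid_col != "id") and nc_levels < 2)]

    best = None
    n_conv = 0
    for structure in structures:
        out = _fit_structure(data, structure)
        if out is None:
            continue
        theta, ll, aux = out
        n_conv += 1
        q = len(theta)
        aic = -2.0 * ll + 2.0 * q
        if best is None or aic < best[0]:
            best = (aic, structure, theta, ll, aux)
    if best is None:
        raise FitError(f"{env}: no candidate structure converged")

    aic, structure, theta, ll, (V, mu, sg2) = best
    sg2_, sr2, sc2, se2, cpar = _unpack(theta, structure)
    # BLUP of genotype effects and PEV under the selected model
    resid = data.y - mu
    Vi = np.linalg.inv(V)
    ones = np.ones(data.n)
    P = Vi - np.outer(Vi @ ones, ones @ Vi) / (ones @ Vi @ ones)
    u_hat = sg2 * (data.Zg.T @ (P @ data.y))
    ZPZ = data.Zg.T @ P @ data.Zg
    pev = np.clip(sg2 - sg2**2 * np.diag(ZPZ), 0.0, None)
    rel = np.clip(1.0 - pev / sg2, 0.0, 1.0) if sg2 > 0 else np.zeros_like(pev)

    genos = list(data.genos.categories)
    vc = {"sigma2_g": sg2, "sigma2_row": sr2, "sigma2_col": sc2, "sigma2_e": se2,
          "row_params": cpar["row_params"], "col_params": cpar["col_params"]}
    return SingleTrialFit(
        environment=env, structure=structure, variance_components=vc,
        genotype_effects=pd.Series(u_hat, index=genos),
        genotype_se=pd.Series(np.sqrt(pev), index=genos),
        sigma2_g=sg2, pev=pd.Series(pev, index=genos),
        reliability=pd.Series(rel, index=genos), loglik=ll, aic=aic,
        mean_reliability=float(np.mean(rel)), n_candidates_converged=n_conv,
    )


def reliability_filter(fits, threshold: float = 0.3):
    """Retain environments whose mean genotype reliability is >= threshold.

    Returns (retained ids, excluded ids).  The comparison is strict: an
    environment at exactly the threshold is retained.
    """
    if not fits:
        raise InputError("no single-trial fits supplied")
    retained = [f.environment for f in fits if not (f.mean_reliability < threshold)]
    excluded = [f.environment for f in fits if f.mean_reliability < threshold]
    if not retained:
        raise FitError("all environments excluded by the reliability filter")
    return retained, excluded
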