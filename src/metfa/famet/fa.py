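"""One-stage factor-analytic MET fitting and post-processing.

``fit_met_fa`` dispatches between the balanced (complete-design) and general
EM engines, wraps results in :class:`FAModelFit`, and supports warm starts
from a lower-order fit.  Post-processing rotates the loadings to the
principal-component solution, computes variance-explained summaries and
converts Ge to genetic correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from ..errors import FitError, InputError
from ..genetics import RelationshipMatrix
from .reml import BalancedEngine, EMEngine
from .single_trial import residual_correlation
from .types import FAModelFit

__all__ = ["fit_met_fa", "rotate_to_pc", "variance_explained",
           "genetic_correlations", "build_b_shapes", "is_complete_design"]


def is_complete_design(plots: pd.DataFrame, kernel: RelationshipMatrix) -> bool:
    sub = plots[plots["genotype"].isin(kernel.ids)]
    counts = sub.groupby(["genotype", "environment"])["yield"].count().unstack()
    if counts.isna().any().any():
        return False
    return bool(counts.eq(counts.iloc[0], axis=1).all().all())


def build_b_shapes(single_fits, plots: pd.DataFrame) -> dict:
    """Fixed non-genetic covariance shapes B_j from single-trial selections.

    B_j = K(ar correlations) + (sigma2_row/sigma2_e) Z_r Z_r'
        + (sigma2_col/sigma2_e) Z_c Z_c', evaluated on the environment's plots
    in (row, col) sort order (the order the MET engines use).
    """
    shapes = {}
    for fit in single_fits:
        env = fit.environment
        sub = plots[plots["environment"] == env].sort_values(["row", "col"], kind="mergesort")
        if sub.empty:
            continue
        rows = sub["row"].to_numpy(int)
        cols = sub["col"].to_numpy(int)
        vc = fit.variance_components
        K = residual_correlation(rows, cols, fit.structure,
                                 {"row_params": vc["row_params"], "col_params": vc["col_params"]})
        se2 = max(vc["sigma2_e"], 1e-12)
        B = K.astype(float)
        if fit.structure.row_effect and vc["sigma2_row"] > 0:
            Zr = (rows[:, None] == np.unique(rows)[None, :]).astype(float)
            B = B + (vc["sigma2_row"] / se2) * Zr @ Zr.T
        if fit.structure.col_effect and vc["sigma2_col"] > 0:
            Zc = (cols[:, None] == np.unique(cols)[None, :]).astype(float)
            B = B + (vc["sigma2_col"] / se2) * Zc @ Zc.T
        shapes[env] = B
    return shapes


def _check_kernel(kernel: RelationshipMatrix):
    w = np.linalg.eigvalsh(kernel.values.to_numpy(float))
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise InputError(f"kernel not PSD (min eigenvalue {w.min():.3g})")


def fit_met_fa(plots: pd.DataFrame, kernel: RelationshipMatrix, k: int = 0,
               start: FAModelFit | None = None, b_shapes: dict | None = None,
               model: str | None = None, engine: str | None = None,
               max_iter: int = 200, tol: float = 1e-6) -> FAModelFit:
    """Fit the one-stage MET model with genetic covariance Ge (x) Gn.

    ``k = 0`` fits the DIAG model, ``k >= 1`` the reduced-rank FA_k model
    (factor-score variances fixed to identity during fitting; scale absorbed
    into the loadings).  ``model="MM"`` fits the genetic-main-effects-only
    baseline.  A ``start`` fit of order k-1 warm-starts the loadings.
    """
    if model is None:
        model = "MM" if k < 0 else ("DIAG" if k == 0 else "FA")
    if model == "FA" and k not in (1, 2, 3):
        raise InputError("k must be in {0 (DIAG), 1, 2, 3}")
    envs = sorted(set(plots["environment"]))
    if model == "FA" and len(envs) < k + 1:
        raise InputError(f"need at least k+1 environments for FA{k}")
    _check_kernel(kernel)
    missing = sorted(set(plots["genotype"]) - set(kernel.ids))

    if engine is None:
        engine = "balanced" if (b_shapes is None and is_complete_design(plots, kernel)) else "em"
    eng = (BalancedEngine(plots, kernel.values) if engine == "balanced"
           else EMEngine(plots, kernel.values, b_shapes=b_shapes))

    start_dict = None
    if start is not None:
        start_dict = {"sig2": start.resid_var.reindex(eng.envs).to_numpy(float)}
        if start.psi is not None:
            start_dict["psi"] = start.psi.reindex(eng.envs).to_numpy(float)
        if start.lam is not None:
            start_dict["lam"] = start.lam.reindex(eng.envs).to_numpy(float)
        if start.sigma2_g is not None:
            start_dict["sg2"] = start.sigma2_g

    res = eng.fit(model, k=k, start=start_dict, max_iter=max_iter, tol=tol)
    if not res["converged"] and model != "MM" and len(res["trajectory"]) >= max_iter:
        # EM hit the iteration cap; keep the fit but flag it
        pass

    p = len(res["envs"])
    n_obs = res["N"]
    if model == "MM":
        q = 1 + p
    elif model == "DIAG":
        q = 2 * p
    else:
        q = p * k - k * (k - 1) // 2 + 2 * p
    ll = res["loglik"]
    aic = -2.0 * ll + 2.0 * q
    bic = -2.0 * ll + q * np.log(max(n_obs - p, 2))

    envs_idx = res["envs"]
    ids = res["ids"]
    lam_df = None
    scores_df = None
    psi_s = None
    d = None
    if model == "FA":
        lam_df = pd.DataFrame(res["lam"], index=envs_idx,
                              columns=[f"fac{r + 1}" for r in range(k)])
        scores_df = pd.DataFrame(res["scores"], index=ids, columns=lam_df.columns)
        psi_s = pd.Series(res["psi"], index=envs_idx)
        d = np.eye(k)
    elif model == "DIAG":
        psi_s = pd.Series(res["psi"], index=envs_idx)

    fit = FAModelFit(
        model=("MM" if model == "MM" else ("DIAG" if model == "DIAG" else f"FA{k}")),
        kernel_kind=kernel.kind, environments=envs_idx, genotype_ids=ids,
        main_effects=pd.Series(res["tau"], index=envs_idx),
        lam=lam_df, d=d, psi=psi_s,
        sigma2_g=res.get("sg2"), scores=scores_df,
        env_effects=pd.DataFrame(res["U"], index=ids, columns=envs_idx),
        resid_var=pd.Series(res["sig2"], index=envs_idx),
        loglik=ll, aic=aic, bic=bic, n_vparams=q,
        converged=res["converged"], trajectory=res["trajectory"],
    )
    fit.dropped_genotypes = missing
    return fit


def rotate_to_pc(fit: FAModelFit) -> FAModelFit:
    """Rotate loadings/scores to the principal-component solution.

    SVD of Lambda gives orthonormal loading columns with factor-score
    variances D equal to the squared singular values (non-increasing);
    genotype scores are counter-rotated so every fitted genetic value
    Lambda f is unchanged.  Sign convention: each factor's loading sum is
    non-negative, and the first factor is majority-positive.
    """
    if fit.lam is None:
        raise InputError("rotation requires an FA fit (k >= 1)")
    lam = fit.lam.to_numpy(float)
    p, k = lam.shape
    U, s, Vt = np.linalg.svd(lam, full_matrices=False)
    keep = s > 1e-12 * max(s.max(), 1.0)
    if keep.sum() < k:
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        k = int(keep.sum())
    lam_rot = U.copy()
    d = s ** 2
    # scores satisfy Lambda f = Lambda_rot f_rot  =>  f_rot = diag(s) V' f
    scores = fit.scores.to_numpy(float) if fit.scores is not None else None
    f_rot = scores @ Vt.T @ np.diag(s) if scores is not None else None

    for r in range(k):
        n_pos = int((lam_rot[:, r] > 0).sum())
        n_neg = int((lam_rot[:, r] < 0).sum())
        flip = (n_pos < n_neg) if r == 0 and n_pos != n_neg else (lam_rot[:, r].sum() < 0)
        if flip:
            lam_rot[:, r] *= -1
            if f_rot is not None:
                f_rot[:, r] *= -1

    cols = [f"fac{r + 1}" for r in range(k)]
    out = FAModelFit(
        model=fit.model, kernel_kind=fit.kernel_kind, environments=fit.environments,
        genotype_ids=fit.genotype_ids,
        main_effects=fit.main_effects,
        lam=pd.DataFrame(lam_rot, index=fit.environments, columns=cols),
        d=np.diag(d), psi=fit.psi, sigma2_g=fit.sigma2_g,
        scores=(pd.DataFrame(f_rot, index=fit.genotype_ids, columns=cols)
                if f_rot is not None else None),
        env_effects=fit.env_effects, resid_var=fit.resid_var,
        loglik=fit.loglik, aic=fit.aic, bic=fit.bic, n_vparams=fit.n_vparams,
        converged=fit.converged, trajectory=fit.trajectory, rotated=True,
        dropped_genotypes=list(fit.dropped_genotypes),
    )
    out.negative_first_loading = [e for e, v in zip(fit.environments, lam_rot[:, 0]) if v < 0]
    return out


def variance_explained(fit: FAModelFit):
    """Percent genetic variance explained per factor and environment.

    v_{r,e} = 100 D_rr Lambda_{e,r}^2 / Ge_{e,e}; the total over factors in
    each environment is 100 (Ge_ee - Psi_e)/Ge_ee, and the overall total is
    v-bar = 100 tr(Lambda D Lambda') / tr(Ge).
    """
    if not fit.rotated:
        raise InputError("variance_explained expects a rotated fit")
    lam = fit.lam.to_numpy(float)
    d = np.diag(fit.d)
    ge_diag = fit.ge().to_numpy().diagonal()
    if np.any(ge_diag <= 0):
        raise FitError("non-positive Ge diagonal")
    per = 100.0 * (lam ** 2) * d[None, :] / ge_diag[:, None]
    per_df = pd.DataFrame(per, index=fit.environments, columns=fit.lam.columns)
    total_per_env = per_df.sum(axis=1)
    vbar = 100.0 * float(np.trace(lam @ np.diag(d) @ lam.T)) / float(ge_diag.sum())
    return per_df, total_per_env, vbar


def genetic_correlations(fit: FAModelFit) -> pd.DataFrame:
    """Convert Ge to the between-environment genetic correlation matrix."""
    ge = fit.ge()
    diag = np.asarray(ge.to_numpy().diagonal(), float)
    if np.any(diag <= 0):
        bad = [e for e, v in zip(fit.environments, diag) if v <= 0]
        raise FitError(f"zero genetic variance in environments: {bad}")
    dinv = 1.0 / np.sqrt(diag)
    corr = ge.to_numpy() * dinv[:, None] * dinv[None, :]
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=fit.environments, columns=fit.environments)
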