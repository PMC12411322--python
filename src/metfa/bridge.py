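"""Second-stage models linking latent environmental effects to covariates.

Environment main effects and factor loadings estimated in the first-stage
mixed model are related to the p x w EC matrix by per-EC correlations with
permutation confidence bands, and predicted by multivariate models that
tolerate w >> p: random forests (500 trees, a third of the covariates tried
per split, node size 5), LASSO (lambda chosen by 10-fold cross-validation on
a fixed grid of 100 values between 1e-8 and 0.04 on standardised
predictors), and partial least squares (component count by inner
leave-one-out cross-validation).  Leave-one-environment-out cross-validation
measures predictive ability; mean-variance or intercept-slope adjustments
correct shrinkage before predictions are extended to environment grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .envirotyping import ECMatrix
from .errors import InputError
from .famet.iclass import iclass_string
from .famet.summaries import env_eblups
from .rng import stream, substream_seed

__all__ = [
    "Stage2Model", "PredictionSet", "correlate_ecs", "fit_stage2",
    "loo_cv_stage2", "adjust_predictions", "predict_extended",
    "iclass_probabilities", "LASSO_LAMBDA_GRID",
]

LASSO_LAMBDA_GRID = np.geomspace(1e-8, 0.04, 100)


@dataclass
class Stage2Model:
    method: str                       # RF | LASSO | PLS
    target: str
    model: object
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: list
    training_environments: list
    importance: pd.Series | None = None
    coefficients: pd.Series | None = None
    chosen: dict = field(default_factory=dict)   # method-specific selections

    def predict(self, ec: ECMatrix | pd.DataFrame) -> pd.Series:
        X = ec.data if isinstance(ec, ECMatrix) else ec
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise InputError(f"EC columns missing from prediction input: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        Z = (X[self.feature_names].to_numpy(float) - self.x_mean) / self.x_sd
        yhat = np.asarray(self.model.predict(Z)).ravel()
        return pd.Series(yhat, index=X.index)


@dataclass
class PredictionSet:
    environment: str
    main_effect: float
    loadings: np.ndarray
    iclass: str
    adjustment: str = "none"
    year: int | None = None
    location: str | None = None

    def __post_init__(self):
        if self.iclass != iclass_string(self.loadings):
            raise InputError("iClass inconsistent with predicted loading signs")


def correlate_ecs(ec: ECMatrix, target: pd.Series, n_perm: int = 1000,
                  seed: int = 0):
    """Pearson correlation of every EC with a target, with permutation bands.

    The null distribution shuffles the target across environments; the band
    is the (2.5, 97.5) percentile envelope of null correlations pooled over
    ECs.  Returns a frame with r, the band, and an outside-band flag.
    """
    X = ec.data
    p = len(X)
    if p < 3:
        raise InputError("need at least 3 environments for correlations")
    y = target.reindex(X.index).to_numpy(float)
    if np.std(y) == 0:
        raise InputError("constant target: correlations undefined")
    Xv = X.to_numpy(float)
    xc = Xv - Xv.mean(axis=0)
    xs = np.sqrt((xc ** 2).sum(axis=0))
    xs[xs == 0] = np.nan
    yc = y - y.mean()
    ys = np.sqrt((yc ** 2).sum())
    r = (xc.T @ yc) / (xs * ys)

    rng = stream(seed, "permutation", target.name or "target")
    null = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        yp = rng.permutation(yc)
        null[b] = (xc.T @ yp) / (xs * ys)
    lo, hi = np.nanpercentile(null, [2.5, 97.5])
    out = pd.DataFrame({"r": r, "lower": lo, "upper": hi}, index=X.columns)
    out["outside_band"] = (out["r"] < lo) | (out["r"] > hi)
    return out


def _standardise_train(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _rf_seed(seed, *keys) -> int:
    return int(substream_seed(seed, *keys).generate_state(1)[0] % (2**31))


def fit_stage2(ec: ECMatrix, target: pd.Series, method: str = "RF",
               seed: int = 0, pls_max_components: int = 10) -> Stage2Model:
    """Fit one second-stage model for one target (a main effect or loading)."""
    X = ec.data
    p, w = X.shape
    if p < 5:
        raise InputError("need at least 5 environments to fit a stage-2 model")
    y = target.reindex(X.index).to_numpy(float)
    if np.isnan(y).any() or X.isna().any().any():
        raise InputError("stage-2 inputs must be complete")
    Z, mu, sd = _standardise_train(X.to_numpy(float))
    name = str(target.name or "target")
    importance = coefficients = None
    chosen = {}

    if method == "RF":
        model = RandomForestRegressor(
            n_estimators=500, max_features=1.0 / 3.0, min_samples_leaf=5,
            random_state=_rf_seed(seed, "rf", name), n_jobs=1)
        model.fit(Z, y)
        importance = pd.Series(model.feature_importances_, index=X.columns)
    elif method == "LASSO":
        rng_seed = _rf_seed(seed, "lasso", name)
        n_folds = min(10, p)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
        cv = LassoCV(alphas=LASSO_LAMBDA_GRID, cv=kf, max_iter=5000, tol=1e-4)
        with np.errstate(all="ignore"):
            cv.fit(Z, y)
        model = Lasso(alpha=cv.alpha_, max_iter=20000)
        model.fit(Z, y)
        coefficients = pd.Series(model.coef_, index=X.columns)
        chosen["lambda"] = float(cv.alpha_)
    elif method == "PLS":
        cap = min(pls_max_components, p - 2, w)
        best_nc, best_err = 1, np.inf
        for nc in range(1, max(cap, 1) + 1):
            errs = []
            for i in range(p):
                tr = np.setdiff1d(np.arange(p), [i])
                m = PLSRegression(n_components=nc, scale=False)
                m.fit(Z[tr], y[tr])
                errs.append((y[i] - float(m.predict(Z[[i]])[0])) ** 2)
            err = float(np.mean(errs))
            if err < best_err:
                best_nc, best_err = nc, err
        model = PLSRegression(n_components=best_nc, scale=False)
        model.fit(Z, y)
        coefficients = pd.Series(model.coef_.ravel(), index=X.columns)
        chosen["n_components"] = best_nc
    else:
        raise InputError(f"unknown stage-2 method '{method}'")

    return Stage2Model(method=method, target=name, model=model, x_mean=mu,
                       x_sd=sd, feature_names=list(X.columns),
                       training_environments=list(X.index),
                       importance=importance, coefficients=coefficients, chosen=chosen)


def loo_cv_stage2(ec: ECMatrix, targets: pd.DataFrame, methods=("RF", "LASSO", "PLS"),
                  seed: int = 0):
    """Leave-one-environment-out CV of every (target, method) pair.

    Returns (metrics frame with predictive ability r and RMSE, out-of-fold
    prediction table).  RMSE uses the number of environments p as
    denominator.  Predictive ability is the fold-centred correlation: both
    the observed and the predicted value of each fold are taken as anomalies
    from that fold's training mean, which removes the leave-one-out
    mean-reversion artifact (a no-signal model that predicts the training
    mean would otherwise score r = -1 rather than 0); a model whose
    predictions carry no signal beyond the training mean scores 0.
    """
    X = ec.data
    p = len(X)
    if p < 5:
        raise InputError("need at least 5 environments for LOO CV")
    rows, preds = [], {}
    for target_name in targets.columns:
        y = targets[target_name].reindex(X.index)
        for method in methods:
            oof = np.full(p, np.nan)
            fold_mean = np.full(p, np.nan)
            for i, env in enumerate(X.index):
                train_envs = [e for e in X.index if e != env]
                sub = ECMatrix(X.loc[train_envs], None)
                m = fit_stage2(sub, y.loc[train_envs], method=method,
                               seed=_rf_seed(seed, "fold", target_name, method, env))
                oof[i] = m.predict(X.loc[[env]]).iloc[0]
                fold_mean[i] = float(y.loc[train_envs].mean())
            ok = np.isfinite(oof)
            obs_anom = y.to_numpy()[ok] - fold_mean[ok]
            pred_anom = oof[ok] - fold_mean[ok]
            if ok.sum() > 2 and np.std(pred_anom) > 1e-12 and np.std(obs_anom) > 0:
                r = float(np.corrcoef(obs_anom, pred_anom)[0, 1])
            elif ok.sum() > 2:
                r = 0.0  # constant (no-signal) predictions
            else:
                r = np.nan
            rmse = float(np.sqrt(np.sum((y.to_numpy()[ok] - oof[ok]) ** 2) / p))
            rows.append((target_name, method, r, rmse, int((~ok).sum())))
            preds[(target_name, method)] = pd.Series(oof, index=X.index)
    metrics = pd.DataFrame(rows, columns=["target", "method", "r", "rmse", "n_failed"])
    pred_df = pd.DataFrame(preds)
    return metrics, pred_df


def adjust_predictions(pred: pd.Series, observed: pd.Series, mode: str = "mean-var"):
    """Correct shrinkage/bias in predictions.

    mean-var: rescale predictions to the observed mean and (e-1)-denominator
    variance.  intercept-slope: apply the coefficients of the
    observed-on-predicted regression (fitted on out-of-fold pairs).
    """
    yp = np.asarray(pred, float)
    if np.std(yp, ddof=0) == 0:
        raise InputError("zero-variance predictions cannot be adjusted")
    if mode == "mean-var":
        yo = observed.reindex(pred.index).to_numpy(float) if isinstance(pred, pd.Series) \
            else np.asarray(observed, float)
        adj = (yp - yp.mean()) / yp.std(ddof=1) * np.std(yo, ddof=1) + yo.mean()
    elif mode == "intercept-slope":
        yo = np.asarray(observed, float)
        slope, intercept = np.polyfit(yp[:len(yo)], yo, 1) if len(yo) == len(yp) else (None, None)
        if slope is None:
            raise InputError("intercept-slope mode needs paired observed values")
        adj = intercept + slope * yp
    else:
        raise InputError(f"unknown adjustment mode '{mode}'")
    if isinstance(pred, pd.Series):
        return pd.Series(adj, index=pred.index)
    return adj


def regression_adjuster(oof_pred: pd.Series, observed: pd.Series):
    """(intercept, slope) of observed ~ out-of-fold predicted."""
    x = oof_pred.to_numpy(float)
    y = observed.reindex(oof_pred.index).to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def predict_extended(models: dict, extended_ec: ECMatrix, fit=None,
                     main_adjuster=None, scores: pd.DataFrame | None = None):
    """Predict main effect, loadings and iClass for extended environments.

    ``models`` maps target name ('main' plus one per factor column) to a
    fitted Stage2Model.  ``main_adjuster`` is an optional (intercept, slope)
    pair applied to the predicted main effects.  Returns (PredictionSet
    list, table); when ``scores`` (or ``fit`` with scores) is given the
    genotype x environment EBLUPs are returned as a third element.
    """
    missing_cols = sorted({c for m in models.values()
                           for c in m.feature_names if c not in extended_ec.data.columns})
    if missing_cols:
        raise InputError(f"extended EC matrix missing columns: {missing_cols}")

    main_pred = models["main"].predict(extended_ec)
    if main_adjuster is not None:
        intercept, slope = main_adjuster
        main_pred = intercept + slope * main_pred
    factor_names = [t for t in models if t != "main"]
    lam_pred = pd.DataFrame(
        {t: models[t].predict(extended_ec) for t in sorted(factor_names)})

    predictions = []
    for env in extended_ec.data.index:
        loadings = lam_pred.loc[env].to_numpy(float)
        loc, _, year = env.rpartition("_")
        predictions.append(PredictionSet(
            environment=env, main_effect=float(main_pred.loc[env]),
            loadings=loadings, iclass=iclass_string(loadings),
            adjustment="intercept-slope" if main_adjuster is not None else "none",
            year=int(year) if year.isdigit() else None, location=loc or None))
    table = pd.DataFrame({
        "environment": [pr.environment for pr in predictions],
        "location": [pr.location for pr in predictions],
        "year": [pr.year for pr in predictions],
        "main_effect": [pr.main_effect for pr in predictions],
        "iclass": [pr.iclass for pr in predictions],
        **{f"fac{r + 1}": [pr.loadings[r] for pr in predictions]
           for r in range(lam_pred.shape[1])},
    }).set_index("environment")

    use_scores = scores if scores is not None else (fit.scores if fit is not None else None)
    if use_scores is not None:
        eblups = env_eblups(use_scores, lam_pred, main_pred)
        return predictions, table, eblups
    return predictions, table


def iclass_probabilities(prediction_table: pd.DataFrame) -> pd.DataFrame:
    """Per-location iClass frequencies over years and the modal class.

    Ties for the modal class break lexicographically (recorded in the
    ``tie`` column).
    """
    if not {"location", "iclass"} <= set(prediction_table.columns):
        raise InputError("prediction table needs 'location' and 'iclass' columns")
    rows = []
    for loc, sub in prediction_table.groupby("location"):
        freqs = sub["iclass"].value_counts(normalize=True).sort_index()
        top = freqs.max()
        modal_candidates = sorted(freqs.index[freqs == top])
        rows.append({"location": loc, "modal_class": modal_candidates[0],
                     "modal_probability": float(top),
                     "tie": len(modal_candidates) > 1,
                     **{f"P({c})": float(v) for c, v in freqs.items()}})
    out = pd.DataFrame(rows).set_index("location").fillna(0.0)
    return out
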