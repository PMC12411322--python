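"""Forward genomic-prediction cross-validation into untested year environments.

Folds are defined by year cutoffs: environments from earlier years train the
models, later years are predicted.  The model ladder compares a genetic
main-effects-only baseline (MM), a diagonal genetic covariance model (DIAG,
training-environment-averaged effects applied to every test environment) and
reduced-rank FA models whose test-environment loadings and main effects are
predicted from ECs by a stage-2 random forest refit inside each fold.
Within-environment predictive ability is measured against genotype effects
estimated from single-trial analyses of each test environment, split by
multi-year check genotypes (tested) versus single-year cohort lines
(untested), and compared to the MM baseline with paired two-tailed t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .bridge import fit_stage2
from .envirotyping import ECMatrix
from .errors import FitError, InputError
from .famet import fit_met_fa, fit_single_trial, rotate_to_pc
from .famet.summaries import env_eblups
from .genetics import RelationshipMatrix
from .rng import substream_seed

__all__ = ["ForwardFold", "forward_folds", "run_forward_cv", "compare_models"]


@dataclass
class ForwardFold:
    fold_id: str
    train_environments: list
    test_environments: list

    def __post_init__(self):
        if set(self.train_environments) & set(self.test_environments):
            raise InputError("train/test environments overlap")


def forward_folds(env_table: pd.DataFrame, cutoffs) -> list:
    """One fold per cutoff year: years < cutoff train, years >= cutoff test."""
    if env_table["year"].nunique() < 2:
        raise InputError("need at least 2 distinct years for forward folds")
    folds = []
    for cutoff in cutoffs:
        train = list(env_table.loc[env_table["year"] < cutoff, "environment"])
        test = list(env_table.loc[env_table["year"] >= cutoff, "environment"])
        if not train or not test:
            raise InputError(f"cutoff {cutoff} leaves an empty train or test set")
        folds.append(ForwardFold(fold_id=f"ge{cutoff}", train_environments=train,
                                 test_environments=test))
    return folds


def _predict_unphenotyped(kernel: RelationshipMatrix, fitted_ids, values: pd.DataFrame,
                          target_ids) -> pd.DataFrame:
    """Kernel regression of fitted genotype values onto additional genotypes."""
    obs = [g for g in fitted_ids if g in kernel.ids]
    new = [g for g in target_ids if g not in set(fitted_ids) and g in kernel.ids]
    out = values.reindex(list(dict.fromkeys(list(fitted_ids) + new)))
    if new:
        Goo = kernel.values.loc[obs, obs].to_numpy(float)
        Gno = kernel.values.loc[new, obs].to_numpy(float)
        ridge = 1e-6 * np.trace(Goo) / len(obs)
        coef = linalg.solve(Goo + ridge * np.eye(len(obs)), values.loc[obs].to_numpy(float),
                            assume_a="pos")
        out.loc[new] = Gno @ coef
    return out


def run_forward_cv(plots: pd.DataFrame, kernel: RelationshipMatrix, ec: ECMatrix,
                   fold: ForwardFold, models=("MM", "DIAG", "FA1", "FA2"),
                   tested_ids=None, seed: int = 0, b_shapes: dict | None = None,
                   single_trial_kwargs: dict | None = None,
                   met_kwargs: dict | None = None) -> pd.DataFrame:
    """Run one forward fold over the model ladder; returns CV result rows.

    ``tested_ids``: genotypes regarded as multi-year checks; by default,
    genotypes observed in more than one distinct training/test year.
    """
    stk = single_trial_kwargs or {}
    mk = met_kwargs or {}
    train_plots = plots[plots["environment"].isin(fold.train_environments)].copy()
    test_plots = plots[plots["environment"].isin(fold.test_environments)].copy()
    if train_plots.empty or test_plots.empty:
        raise InputError("fold has no train or test plots")

    if tested_ids is None:
        yrs = plots.groupby("genotype")["year"].nunique()
        tested_ids = set(yrs.index[yrs > 1])
    else:
        tested_ids = set(tested_ids)

    # ground truth: genotype effects from single-trial fits of each test env
    truth = {}
    for env in fold.test_environments:
        sub = test_plots[test_plots["environment"] == env]
        try:
            truth[env] = fit_single_trial(sub, environment=env, **stk).genotype_effects
        except FitError:
            continue

    # model ladder on training plots only
    fits = {}
    prev = None
    for m in models:
        if m == "MM":
            fits[m] = fit_met_fa(train_plots, kernel, model="MM",
                                 b_shapes=b_shapes, **mk)
        elif m == "DIAG":
            fits[m] = fit_met_fa(train_plots, kernel, k=0, b_shapes=b_shapes, **mk)
            prev = fits[m]
        elif m.startswith("FA"):
            k = int(m[2:])
            fits[m] = fit_met_fa(train_plots, kernel, k=k, start=prev,
                                 b_shapes=b_shapes, **mk)
            prev = fits[m]
        else:
            raise InputError(f"unknown model '{m}'")

    test_ec = ec.subset([e for e in fold.test_environments if e in ec.data.index])
    train_ec = ec.subset([e for e in fold.train_environments if e in ec.data.index])

    rows = []
    for m in models:
        fit = fits[m]
        if m == "MM":
            geno_pred = pd.DataFrame(
                {env: pd.Series(fit.env_effects.iloc[:, 0], index=fit.genotype_ids)
                 for env in fold.test_environments})
        elif m == "DIAG":
            avg = fit.env_effects.mean(axis=1)
            geno_pred = pd.DataFrame({env: avg for env in fold.test_environments})
        else:
            rot = rotate_to_pc(fit)
            targets = rot.lam.copy()
            targets["main"] = rot.main_effects
            s2_models = {}
            for tname in list(rot.lam.columns) + ["main"]:
                tseed = int(substream_seed(seed, "stage2", fold.fold_id, m, tname)
                            .generate_state(1)[0] % (2**31))
                s2_models[tname] = fit_stage2(train_ec, targets[tname], method="RF",
                                              seed=tseed)
            lam_pred = pd.DataFrame(
                {c: s2_models[c].predict(test_ec) for c in rot.lam.columns})
            main_pred = s2_models["main"].predict(test_ec)
            geno_pred = env_eblups(rot.scores, lam_pred, main_pred)
        # extend to genotypes present in test plots but absent from training fit
        geno_pred = _predict_unphenotyped(
            kernel, list(geno_pred.index), geno_pred,
            sorted(set(test_plots["genotype"])))

        for env in fold.test_environments:
            if env not in truth or env not in geno_pred.columns:
                continue
            obs = truth[env]
            for group, members in (("tested", [g for g in obs.index if g in tested_ids]),
                                   ("untested", [g for g in obs.index if g not in tested_ids])):
                common = [g for g in members if g in geno_pred.index]
                if len(common) < 3:
                    continue
                o = obs.loc[common].to_numpy(float)
                pvals = geno_pred.loc[common, env].to_numpy(float)
                if np.std(o) == 0 or np.std(pvals) == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(o, pvals)[0, 1])
                rmse = float(np.sqrt(np.mean((o - pvals) ** 2)))
                rows.append((fold.fold_id, m, env, group, r, rmse, len(common)))

    return pd.DataFrame(rows, columns=["fold", "model", "environment", "group",
                                       "r", "rmse", "n_genotypes"])


def compare_models(results: pd.DataFrame, baseline: str = "MM",
                   group: str | None = None) -> pd.DataFrame:
    """Paired two-tailed t-tests of within-environment predictive ability
    against the baseline model, per fold (and per genotype group)."""
    out = []
    sub = results if group is None else results[results["group"] == group]
    for (fold, grp), block in sub.groupby(["fold", "group"]):
        base = block[block["model"] == baseline].set_index("environment")["r"]
        for model in block["model"].unique():
            if model == baseline:
                continue
            other = block[block["model"] == model].set_index("environment")["r"]
            common = base.index.intersection(other.index)
            if len(common) < 3:
                out.append((fold, grp, model, np.nan, len(common), np.nan, np.nan,
                            "fewer than 3 paired environments"))
                continue
            d = (other.loc[common] - base.loc[common]).to_numpy(float)
            if np.allclose(d.std(ddof=1), 0.0):
                if np.allclose(d.mean(), 0.0):
                    t, pv = 0.0, 1.0
                else:  # constant nonzero difference: capped statistic
                    t, pv = np.sign(d.mean()) * 1e6, 0.0
            else:
                t, pv = stats.ttest_rel(other.loc[common], base.loc[common])
            out.append((fold, grp, model, float(d.mean()), len(common),
                        float(t), float(pv), ""))
    return pd.DataFrame(out, columns=["fold", "group", "model", "mean_diff",
                                      "n_pairs", "t", "p", "note"])
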