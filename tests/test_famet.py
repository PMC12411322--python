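"""Mixed-model stack: single-trial selection, REML engines, FA post-processing."""

import numpy as np
import pandas as pd
import pytest

from metfa.errors import FitError, InputError
from metfa.famet import (BalancedEngine, EMEngine, assign_iclasses, dense_reml_loglik,
                         env_eblups, fit_met_fa, fit_single_trial, genetic_correlations,
                         genotype_summaries, reliability_filter, rotate_to_pc,
                         variance_explained)
from metfa.famet.types import FAModelFit, SingleTrialFit, TrialStructure
from metfa.genetics import RelationshipMatrix

from conftest import balanced_met


def _trial(seed=0, n_geno=40, reps=2, sg2=0.4, sr2=0.0, sc2=0.0, se2=0.15,
           rho_r=0.0, rho_c=0.0):
    rng = np.random.default_rng(seed)
    genos = [f"g{i}" for i in range(n_geno)]
    nplots = n_geno * reps
    ncol = 8
    nrow = int(np.ceil(nplots / ncol))
    u = rng.normal(0, np.sqrt(sg2), n_geno)
    re = rng.normal(0, np.sqrt(sr2), nrow) if sr2 else np.zeros(nrow)
    ce = rng.normal(0, np.sqrt(sc2), ncol) if sc2 else np.zeros(ncol)
    # separable AR field
    def ar1(n, rho):
        idx = np.arange(n)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    field = (np.linalg.cholesky(ar1(nrow, rho_r) + 1e-10 * np.eye(nrow))
             @ rng.normal(size=(nrow, ncol))
             @ np.linalg.cholesky(ar1(ncol, rho_c) + 1e-10 * np.eye(ncol)).T
             ) * np.sqrt(se2)
    rows = []
    slot = 0
    for i, g in enumerate(genos):
        for _ in range(reps):
            r, c = slot // ncol, slot % ncol
            rows.append(("T1", 2020, "L", g, r + 1, c + 1,
                         4.0 + u[i] + re[r] + ce[c] + field[r, c]))
            slot += 1
    return pd.DataFrame(rows, columns=["environment", "year", "location",
                                       "genotype", "row", "col", "yield"]), u


class TestSingleTrial:
    def test_independent_structure_favoured_when_simulated(self):
        # With no spatial signal, boundary variance components (row/col random
        # effects) give near-zero likelihood gain and rarely survive the AIC
        # penalty; a spurious ar1 correlation is an interior parameter whose
        # deviance is ~ chi2(1), so it wins AIC with probability ~0.16 per
        # direction -- the independent model should still be selected in about
        # half the seeds and spatial random effects in very few.
        no_rowcol = full_id = 0
        for seed in range(10):
            plots, _ = _trial(seed=seed)
            fit = fit_single_trial(plots)
            s = fit.structure
            no_rowcol += not s.row_effect and not s.col_effect
            full_id += (not s.row_effect and not s.col_effect
                        and s.resid_row == "id" and s.resid_col == "id")
        assert no_rowcol >= 8
        assert full_id >= 4

    def test_duplicate_coordinates_rejected(self):
        plots, _ = _trial()
        plots.loc[1, ["row", "col"]] = plots.loc[0, ["row", "col"]]
        with pytest.raises(InputError):
            fit_single_trial(plots)

    def test_genotype_effects_correlate_with_truth(self):
        plots, u = _trial(seed=3)
        fit = fit_single_trial(plots)
        est = fit.genotype_effects.reindex([f"g{i}" for i in range(len(u))])
        assert np.corrcoef(est, u)[0, 1] > 0.8
        assert 0 < fit.mean_reliability <= 1

    def test_reliability_endpoints(self):
        # PEV = sigma2_G -> reliability 0; PEV = 0 -> reliability 1
        rel = lambda pev, sg2: np.clip(1 - pev / sg2, 0, 1)
        assert rel(0.4, 0.4) == 0.0
        assert rel(0.0, 0.4) == 1.0

    def test_reliability_filter_boundary_semantics(self):
        def stub(env, mean_rel):
            return SingleTrialFit(
                environment=env, structure=TrialStructure(False, False, "id", "id"),
                variance_components={}, genotype_effects=pd.Series(dtype=float),
                genotype_se=pd.Series(dtype=float), sigma2_g=1.0,
                pev=pd.Series(dtype=float), reliability=pd.Series(dtype=float),
                loglik=0.0, aic=0.0, mean_reliability=mean_rel)
        retained, excluded = reliability_filter([stub("A", 0.29), stub("B", 0.30),
                                                 stub("C", 1.0)])
        assert retained == ["B", "C"] and excluded == ["A"]
        with pytest.raises(FitError):
            reliability_filter([stub("A", 0.1)])

    def test_pure_noise_environment_excluded(self):
        # replicated design keeps genetic and residual variance identifiable
        excluded_count = 0
        for seed in range(10):
            plots, _ = _trial(seed=seed, sg2=1e-4, se2=1.0, n_geno=90, reps=2)
            fit = fit_single_trial(plots)
            excluded_count += fit.mean_reliability < 0.3
        assert excluded_count >= 9


@pytest.fixture(scope="module")
def tiny_balanced():
    return balanced_met(seed=1, n=30, p=4, k=1)


class TestREMLEngines:
    def test_objective_matches_dense_oracle_at_optimum(self, tiny_balanced):
        d = tiny_balanced
        kern = RelationshipMatrix(d["kernel"], "GRM")
        fit = fit_met_fa(d["plots"], kern, k=1, engine="balanced")
        lam = fit.lam.to_numpy()
        ge = lam @ lam.T + np.diag(fit.psi.to_numpy())
        ll_oracle = dense_reml_loglik(d["plots"], d["kernel"], ge,
                                      fit.resid_var.to_numpy(), fit.environments)
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-4)

    def test_em_and_balanced_engines_agree(self, tiny_balanced):
        d = tiny_balanced
        kern = RelationshipMatrix(d["kernel"], "GRM")
        f_fast = fit_met_fa(d["plots"], kern, k=1, engine="balanced")
        f_em = fit_met_fa(d["plots"], kern, k=1, engine="em", max_iter=500, tol=1e-9)
        assert f_em.loglik == pytest.approx(f_fast.loglik, abs=5e-3)
        assert np.allclose(np.sort(f_em.main_effects), np.sort(f_fast.main_effects),
                           atol=0.02)

    def test_em_trajectory_monotone(self, tiny_balanced):
        d = tiny_balanced
        kern = RelationshipMatrix(d["kernel"], "GRM")
        fit = fit_met_fa(d["plots"], kern, k=1, engine="em", max_iter=300, tol=1e-9)
        traj = fit.trajectory
        assert all(b >= a - 1e-8 for a, b in zip(traj, traj[1:]))

    def test_nested_model_likelihood_ordering(self, tiny_balanced):
        d = tiny_balanced
        kern = RelationshipMatrix(d["kernel"], "GRM")
        diag = fit_met_fa(d["plots"], kern, k=0)
        fa1 = fit_met_fa(d["plots"], kern, k=1, start=diag)
        fa2 = fit_met_fa(d["plots"], kern, k=2, start=fa1)
        assert fa1.loglik >= diag.loglik - 1e-6
        assert fa2.loglik >= fa1.loglik - 1e-6

    def test_diag_matches_independent_per_env_fits(self):
        d = balanced_met(seed=5, n=40, p=4, k=1, psi=0.0, lam_scale=(0.5, 0.8))
        kern = RelationshipMatrix(d["kernel"], "GRM")
        fit = fit_met_fa(d["plots"], kern, k=0)
        # environment-wise oracle: fit each environment separately
        for j, env in enumerate(fit.environments):
            sub = d["plots"][d["plots"]["environment"] == env]
            single = fit_met_fa(sub, kern, k=0)
            assert fit.psi[env] == pytest.approx(single.psi[env], rel=0.05, abs=0.02)

    def test_non_psd_kernel_rejected(self, tiny_balanced):
        d = tiny_balanced
        bad = d["kernel"].copy()
        np.fill_diagonal(bad.to_numpy(), -1.0)
        bad = (bad + bad.T) / 2
        with pytest.raises(InputError):
            fit_met_fa(d["plots"], RelationshipMatrix(bad, "GRM"), k=1)

    def test_parameter_recovery_p12_n200(self):
        # k_true = 2, p = 12, n = 200, 2 reps: genetic-correlation MAE and
        # factor-1 sign recovery over seeds
        maes, signs = [], []
        for seed in range(10):
            d = balanced_met(seed=seed, n=200, p=12, k=2, psi=0.05, resid=0.2)
            kern = RelationshipMatrix(d["kernel"], "GRM")
            fit = rotate_to_pc(fit_met_fa(d["plots"], kern, k=2))
            ge_hat = fit.ge().to_numpy()
            dh = 1 / np.sqrt(np.diag(ge_hat))
            ch = ge_hat * dh[:, None] * dh[None, :]
            ge_true = d["Ge"]
            dt = 1 / np.sqrt(np.diag(ge_true))
            ct = ge_true * dt[:, None] * dt[None, :]
            iu = np.triu_indices(12, 1)
            maes.append(np.abs(ch[iu] - ct[iu]).mean())
            # rotate the truth the same way for factor-1 comparison
            Ut, st, _ = np.linalg.svd(d["lam"], full_matrices=False)
            t1 = Ut[:, 0] * np.sign(Ut[:, 0].sum())
            l1 = fit.lam.to_numpy()[:, 0]
            signs.append((np.sign(l1) == np.sign(t1)).mean())
        assert np.mean(maes) <= 0.15
        assert np.mean(signs) >= 0.90


class TestRotation:
    def test_rotation_invariances(self, tiny_balanced):
        d = balanced_met(seed=2, n=40, p=8, k=3, psi=0.05)
        kern = RelationshipMatrix(d["kernel"], "GRM")
        fit = fit_met_fa(d["plots"], kern, k=3)
        rot = rotate_to_pc(fit)
        lam0 = fit.lam.to_numpy()
        lam1 = rot.lam.to_numpy()
        assert np.abs(lam0 @ lam0.T - lam1 @ rot.d @ lam1.T).max() < 1e-8
        # fitted common genetic values unchanged
        gv0 = fit.scores.to_numpy() @ lam0.T
        gv1 = rot.scores.to_numpy() @ lam1.T
        assert np.abs(gv0 - gv1).max() < 1e-8
        # D non-increasing, equals squared singular values
        dvals = np.diag(rot.d)
        assert all(b <= a + 1e-12 for a, b in zip(dvals, dvals[1:]))
        assert np.allclose(np.sort(dvals)[::-1],
                           np.sort(np.linalg.svd(lam0, compute_uv=False) ** 2)[::-1])

    def test_k1_rotation_is_sign_flip(self):
        lam = pd.DataFrame({"fac1": [-0.5, -0.7, -0.6]}, index=list("abc"))
        scores = pd.DataFrame({"fac1": [1.0, -2.0]}, index=["g1", "g2"])
        fit = FAModelFit(model="FA1", kernel_kind="GRM", environments=list("abc"),
                         genotype_ids=["g1", "g2"], main_effects=pd.Series(0, index=list("abc")),
                         lam=lam, d=np.eye(1), psi=pd.Series(0.1, index=list("abc")),
                         sigma2_g=None, scores=scores,
                         env_effects=pd.DataFrame(0.0, index=["g1", "g2"], columns=list("abc")),
                         resid_var=pd.Series(0.1, index=list("abc")),
                         loglik=0, aic=0, bic=0, n_vparams=1, converged=True)
        rot = rotate_to_pc(fit)
        norm = np.linalg.norm(lam.to_numpy())
        assert np.allclose(np.abs(rot.lam.to_numpy().ravel()),
                           np.abs(lam.to_numpy().ravel()) / norm)
        assert (rot.lam.to_numpy() > 0).all()  # sign convention


class TestVarianceExplained:
    def _fit_from(self, lam, psi, d=None):
        p, k = lam.shape
        envs = [f"e{j}" for j in range(p)]
        return FAModelFit(
            model=f"FA{k}", kernel_kind="GRM", environments=envs, genotype_ids=["g"],
            main_effects=pd.Series(0.0, index=envs),
            lam=pd.DataFrame(lam, index=envs, columns=[f"fac{r+1}" for r in range(k)]),
            d=d if d is not None else np.eye(k),
            psi=pd.Series(psi, index=envs), sigma2_g=None,
            scores=pd.DataFrame(np.zeros((1, k)), index=["g"],
                                columns=[f"fac{r+1}" for r in range(k)]),
            env_effects=pd.DataFrame(0.0, index=["g"], columns=envs),
            resid_var=pd.Series(1.0, index=envs), loglik=0, aic=0, bic=0,
            n_vparams=0, converged=True, rotated=True)

    def test_psi_zero_gives_100pct_totals(self):
        lam = np.array([[0.5, 0.2], [0.7, -0.3], [0.4, 0.6]])
        fit = self._fit_from(lam, psi=np.zeros(3))
        per, totals, vbar = variance_explained(fit)
        assert np.allclose(totals, 100.0)
        assert vbar == pytest.approx(100.0)

    def test_equal_split_50pct(self):
        lam = np.array([[0.5], [0.8]])
        fit = self._fit_from(lam, psi=lam[:, 0] ** 2)
        per, totals, vbar = variance_explained(fit)
        assert np.allclose(per.to_numpy(), 50.0)

    def test_matches_direct_matrix_arithmetic(self):
        rng = np.random.default_rng(11)
        lam = rng.normal(size=(6, 2))
        psi = rng.uniform(0.05, 0.3, 6)
        d = np.diag([2.0, 0.7])
        fit = self._fit_from(lam, psi, d=d)
        per, totals, vbar = variance_explained(fit)
        ge = lam @ d @ lam.T + np.diag(psi)
        for j in range(6):
            for r in range(2):
                assert per.iloc[j, r] == pytest.approx(
                    100 * d[r, r] * lam[j, r] ** 2 / ge[j, j])
        assert vbar == pytest.approx(100 * np.trace(lam @ d @ lam.T) / np.trace(ge))

    def test_correlations_match_cov2cor_oracle(self):
        rng = np.random.default_rng(12)
        lam = rng.normal(size=(5, 2))
        psi = rng.uniform(0.05, 0.3, 5)
        fit = self._fit_from(lam, psi)
        corr = genetic_correlations(fit).to_numpy()
        ge = lam @ lam.T + np.diag(psi)
        dinv = np.diag(1 / np.sqrt(np.diag(ge)))
        assert np.allclose(corr, dinv @ ge @ dinv, atol=1e-12)
        assert np.allclose(np.diag(corr), 1.0)

    def test_rank1_full_correlation(self):
        lam = np.array([[0.5], [0.8], [-0.3]])
        fit = self._fit_from(lam, psi=np.zeros(3) + 1e-12)
        corr = genetic_correlations(fit).to_numpy()
        assert np.allclose(np.abs(corr), 1.0, atol=1e-6)
        assert corr[0, 2] < 0


class TestIClass:
    def _fit(self, lam, scores=None):
        p, k = lam.shape
        envs = [f"e{j}" for j in range(p)]
        n = 3 if scores is None else scores.shape[0]
        scores = np.zeros((n, k)) if scores is None else scores
        return FAModelFit(
            model=f"FA{k}", kernel_kind="GRM", environments=envs,
            genotype_ids=[f"g{i}" for i in range(n)],
            main_effects=pd.Series(0.0, index=envs),
            lam=pd.DataFrame(lam, index=envs, columns=[f"fac{r+1}" for r in range(k)]),
            d=np.eye(k), psi=pd.Series(0.05, index=envs), sigma2_g=None,
            scores=pd.DataFrame(scores, index=[f"g{i}" for i in range(n)],
                                columns=[f"fac{r+1}" for r in range(k)]),
            env_effects=pd.DataFrame(0.0, index=[f"g{i}" for i in range(n)], columns=envs),
            resid_var=pd.Series(1.0, index=envs), loglik=0, aic=0, bic=0,
            n_vparams=0, converged=True, rotated=True)

    def test_sign_rule(self):
        from metfa.famet import iclass_string
        assert iclass_string([0.8, 0.3, -0.2]) == "ppn"
        assert iclass_string([0.0, -0.1]) == "pn"  # zero -> 'p'

    def test_class_count_bounded_by_2k(self):
        rng = np.random.default_rng(13)
        lam = rng.normal(size=(40, 3))
        fit = self._fit(lam)
        corr = genetic_correlations(fit)
        ic = assign_iclasses(fit, corr)
        assert ic.classes.nunique() <= 8

    def test_singleton_merged_into_highest_mean_correlation_class(self):
        # constructed case: e0..e2 'pp', e3..e4 'pn', e5 alone 'np'
        lam = np.array([[0.8, 0.5], [0.7, 0.4], [0.9, 0.6],
                        [0.8, -0.5], [0.7, -0.4], [-0.2, 0.3]])
        fit = self._fit(lam)
        corr = genetic_correlations(fit)
        ic = assign_iclasses(fit, corr)
        # hand computation: mean corr of e5 with pp class vs pn class
        mean_pp = corr.loc["e5", ["e0", "e1", "e2"]].mean()
        mean_pn = corr.loc["e5", ["e3", "e4"]].mean()
        expected = "pp" if mean_pp > mean_pn else "pn"
        assert ic.classes["e5"] == expected
        assert ic.merge_log[0][0] == "e5"
        assert (ic.classes.value_counts() > 1).all()


class TestSummaries:
    def test_k1_rmsd_zero_and_op_formula(self):
        lam = np.array([[0.5], [0.5]])
        scores = np.array([[2.0], [-1.0]])
        fit = TestIClass()._fit(lam, scores)
        corr = genetic_correlations(fit)
        ic = assign_iclasses(fit, corr)
        summ = genotype_summaries(fit, ic)
        assert np.allclose(summ.rmsd, 0.0)
        assert summ.op["g0"] == pytest.approx(0.5 * 2.0)  # mean loading x score

    def test_three_env_k2_spreadsheet_oracle(self):
        lam = np.array([[0.6, 0.2], [0.5, -0.3], [0.7, 0.1]])
        scores = np.array([[1.0, 0.5], [-0.5, 1.5]])
        fit = TestIClass()._fit(lam, scores)
        corr = genetic_correlations(fit)
        ic = assign_iclasses(fit, corr)
        summ = genotype_summaries(fit, ic)
        assert summ.op["g0"] == pytest.approx(lam[:, 0].mean() * 1.0)
        # single class after merging: iClassOP = mean loadings . scores
        w = ic.classes.unique()[0]
        lam_bar = lam.mean(axis=0)
        assert summ.iclass_op.loc["g0", w] == pytest.approx(lam_bar @ scores[0])
        dev0 = scores[0, 1] * lam[:, 1]
        assert summ.rmsd["g0"] == pytest.approx(np.sqrt(np.mean(dev0 ** 2)))

    def test_env_eblups(self):
        scores = pd.DataFrame([[1.0, 0.0], [0.0, 2.0]], index=["g0", "g1"],
                              columns=["fac1", "fac2"])
        lam_new = pd.DataFrame([[0.5, 0.1], [0.0, 0.0]], index=["x1", "x2"],
                               columns=["fac1", "fac2"])
        mains = pd.Series([3.0, 4.0], index=["x1", "x2"])
        pred = env_eblups(scores, lam_new, mains)
        assert pred.loc["g0", "x1"] == pytest.approx(3.0 + 0.5)
        assert pred.loc["g1", "x1"] == pytest.approx(3.0 + 0.2)
        # zero loadings -> predictions equal main effects
        assert pred.loc["g0", "x2"] == pytest.approx(4.0)
        with pytest.raises(InputError):
            env_eblups(scores, lam_new[["fac1"]], mains)
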