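"""REML engines for the one-stage MET model.

Model: y = X tau + Z u + e, with fixed environment main effects tau, genetic
effects u ordered environment-major with covariance Ge (x) Gn (Kronecker),
and block-diagonal non-genetic covariance R with per-environment blocks
sigma2_j * B_j (B_j a fixed shape carrying the spatial structure selected in
the single-trial stage; identity by default).

Ge is structured as MM (constant: sigma2_g * J), DIAG (diagonal) or FA_k
(Lambda Lambda' + Psi, factor-score variances fixed to identity during
fitting with the scale absorbed into the loadings).

Two engines maximise the same residual likelihood:

* ``EMEngine`` - EM-REML on the mixed-model equations in the whitened
  genotype basis u = (I_p x Q Gamma^{1/2}) w (Gn eigendecomposition), with
  closed-form monotone updates.  Handles arbitrary sparse designs and fixed
  spatial shapes.
* ``BalancedEngine`` - direct quasi-Newton maximisation of the analytically
  reduced likelihood for complete genotype x environment designs with
  independent residuals, where the Gn eigenbasis makes every likelihood
  evaluation O(n p^2).

Both report the exact REML log-likelihood (constants included) so the
objective can be compared against a dense-matrix evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from ..errors import FitError, InputError

_LOG2PI = np.log(2.0 * np.pi)
_PSI_FLOOR = 1e-8
_SIG_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _fa_inner_em(S: np.ndarray, lam0: np.ndarray, psi0: np.ndarray,
                 n_iter: int = 60, tol: float = 1e-10):
    """Fit Lambda, Psi to a p x p covariance S by factor-analysis EM.

    Monotone in the Gaussian objective -(log|Ge| + tr(Ge^{-1} S)).
    """
    lam, psi = lam0.copy(), psi0.copy()
    p, k = lam.shape
    prev = None
    for _ in range(n_iter):
        ge = lam @ lam.T + np.diag(psi)
        gi = linalg.inv(ge)
        beta = lam.T @ gi                      # k x p
        eff = np.eye(k) - beta @ lam + beta @ S @ beta.T
        lam = S @ beta.T @ linalg.inv(eff)
        psi = np.clip(np.diag(S - lam @ beta @ S), _PSI_FLOOR * np.trace(S) / p, None)
        obj = -(np.linalg.slogdet(lam @ lam.T + np.diag(psi))[1]
                + np.trace(linalg.solve(lam @ lam.T + np.diag(psi), S)))
        if prev is not None and abs(obj - prev) < tol * abs(prev):
            break
        prev = obj
    return lam, psi


def _kernel_eigen(Gn: np.ndarray, tol: float = 1e-8):
    """Reduced-rank whitening of the genotype kernel: Gn ~ Q diag(gam) Q'."""
    w, V = np.linalg.eigh((Gn + Gn.T) / 2.0)
    keep = w > tol * max(w.max(), 1.0)
    return V[:, keep], w[keep]


# ---------------------------------------------------------------------------
# general EM engine
# ---------------------------------------------------------------------------

class EMEngine:
    """EM-REML on the mixed-model equations for arbitrary MET designs."""

    def __init__(self, plots: pd.DataFrame, kernel_values: pd.DataFrame,
                 b_shapes: dict | None = None):
        plots = plots.sort_values(["environment", "row", "col"], kind="mergesort").reset_index(drop=True)
        self.envs = list(dict.fromkeys(plots["environment"]))
        ids = list(kernel_values.index)
        in_kernel = plots["genotype"].isin(ids)
        self.dropped_genotypes = sorted(set(plots.loc[~in_kernel, "genotype"]))
        plots = plots[in_kernel].reset_index(drop=True)
        self.plots = plots
        self.ids = [g for g in ids if g in set(plots["genotype"])]
        gidx = {g: i for i, g in enumerate(self.ids)}
        Gn = kernel_values.loc[self.ids, self.ids].to_numpy(float)
        self.Q, self.gam = _kernel_eigen(Gn)
        self.r = len(self.gam)
        QL = self.Q * np.sqrt(self.gam)[None, :]        # n x r

        self.p = len(self.envs)
        self.n = len(self.ids)
        self.blocks = []
        self.N = 0
        for env in self.envs:
            sub = plots[plots["environment"] == env]
            y = sub["yield"].to_numpy(float)
            Nj = len(y)
            self.N += Nj
            Zt = QL[[gidx[g] for g in sub["genotype"]], :]  # Nj x r
            if b_shapes is not None and env in b_shapes:
                B = np.asarray(b_shapes[env], float)
                if B.shape != (Nj, Nj):
                    raise InputError(f"B shape for {env} mismatched to its plot count")
                Bl = np.linalg.cholesky(B)
                logdetB = 2.0 * np.sum(np.log(np.diag(Bl)))
                Binv = linalg.cho_solve((Bl, True), np.eye(Nj))
            else:
                Binv = np.eye(Nj)
                logdetB = 0.0
            one = np.ones(Nj)
            self.blocks.append({
                "env": env, "y": y, "Zt": Zt, "Nj": Nj, "logdetB": logdetB,
                "Binv": Binv,
                "xbx": one @ Binv @ one, "xbz": one @ Binv @ Zt,
                "zbz": Zt.T @ Binv @ Zt, "xby": one @ Binv @ y,
                "zby": Zt.T @ Binv @ y, "yby": y @ Binv @ y,
                "Bi_y": Binv @ y, "Bi_one": Binv @ one, "Bi_Z": Binv @ Zt,
            })

    # -- one EM pass ---------------------------------------------------------
    def _assemble(self, ge_inv: np.ndarray, sig2: np.ndarray):
        p, r = self.p, self.r
        dim = p + p * r
        M = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        for j, blk in enumerate(self.blocks):
            s = sig2[j]
            w0 = p + j * r
            M[j, j] = blk["xbx"] / s
            M[j, w0:w0 + r] = blk["xbz"] / s
            M[w0:w0 + r, j] = blk["xbz"] / s
            M[w0:w0 + r, w0:w0 + r] = blk["zbz"] / s
            rhs[j] = blk["xby"] / s
            rhs[w0:w0 + r] = blk["zby"] / s
        for j in range(p):
            for l in range(p):
                M[p + j * r:p + (j + 1) * r, p + l * r:p + (l + 1) * r] += (
                    ge_inv[j, l] * np.eye(r))
        return M, rhs

    def _loglik_and_moments(self, Ge: np.ndarray, sig2: np.ndarray):
        p, r = self.p, self.r
        sign, logdet_ge = np.linalg.slogdet(Ge)
        if sign <= 0:
            raise FitError("Ge not positive definite")
        ge_inv = linalg.inv(Ge)
        M, rhs = self._assemble(ge_inv, sig2)
        try:
            cf = linalg.cho_factor(M, lower=True)
        except linalg.LinAlgError as exc:
            raise FitError(f"MME not positive definite: {exc}") from exc
        sol = linalg.cho_solve(cf, rhs)
        C = linalg.cho_solve(cf, np.eye(M.shape[0]))
        logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
        log_R = sum(blk["Nj"] * np.log(sig2[j]) + blk["logdetB"]
                    for j, blk in enumerate(self.blocks))
        ypy = sum(blk["yby"] / sig2[j] for j, blk in enumerate(self.blocks)) - rhs @ sol
        ll = -0.5 * ((self.N - p) * _LOG2PI + log_R + r * logdet_ge + logdet_M + ypy)
        return ll, sol, C

    def _em_updates(self, sol, C, sig2):
        p, r = self.p, self.r
        W = sol[p:].reshape(p, r).T            # r x p matrix of w-hat
        S = W.T @ W
        for j in range(p):
            for l in range(j, p):
                tr = np.trace(C[p + j * r:p + (j + 1) * r, p + l * r:p + (l + 1) * r])
                S[j, l] += tr
                if l != j:
                    S[l, j] += tr
        S /= r
        new_sig = np.empty(p)
        for j, blk in enumerate(self.blocks):
            w0 = p + j * r
            tau_j = sol[j]
            wj = sol[w0:w0 + r]
            e = blk["y"] - tau_j - blk["Zt"] @ wj
            quad = e @ blk["Binv"] @ e
            idxs = np.concatenate(([j], np.arange(w0, w0 + r)))
            Csub = C[np.ix_(idxs, idxs)]
            Wd = np.column_stack([np.ones(blk["Nj"]), blk["Zt"]])
            BiW = np.column_stack([blk["Bi_one"], blk["Bi_Z"]])
            tr = float(np.sum(BiW * (Wd @ Csub)))
            new_sig[j] = max((quad + tr) / blk["Nj"], _SIG_FLOOR)
        return S, new_sig, W

    def fit(self, model: str, k: int = 0, start: dict | None = None,
            max_iter: int = 200, tol: float = 1e-6):
        """Run EM to convergence.  model in {"MM", "DIAG", "FA"}."""
        if model == "MM":
            return self._fit_mm(start, max_iter, tol)
        p = self.p
        y_var = np.array([np.var(b["y"]) for b in self.blocks])
        if start is None:
            psi = 0.5 * y_var + 1e-3
            sig2 = 0.5 * y_var + 1e-3
            lam = None
            if model == "FA":
                rng = np.random.default_rng(0)
                lam = 0.3 * np.sqrt(np.mean(psi)) * (1.0 + 0.1 * rng.standard_normal((p, k)))
                psi = 0.5 * psi
        else:
            sig2 = np.asarray(start.get("sig2", 0.5 * y_var + 1e-3), float).copy()
            psi = np.asarray(start["psi"], float).copy()
            lam = None
            if model == "FA":
                if start.get("lam") is None:
                    # warm start from DIAG: move half the specific variance
                    # into a seeded first loading column
                    rng = np.random.default_rng(1 + k)
                    lam = (np.sqrt(0.5 * psi)[:, None]
                           * (1.0 + 0.1 * rng.standard_normal((p, k))))
                    psi = 0.5 * psi
                else:
                    lam = np.asarray(start["lam"], float).copy()
                    if lam.shape[1] < k:
                        rng = np.random.default_rng(1 + k)
                        extra = 0.05 * np.sqrt(np.mean(psi)) * rng.standard_normal(
                            (p, k - lam.shape[1]))
                        lam = np.column_stack([lam, extra])

        traj = []
        converged = False
        for _ in range(max_iter):
            Ge = np.diag(psi) if model == "DIAG" else lam @ lam.T + np.diag(psi)
            ll, sol, C = self._loglik_and_moments(Ge, sig2)
            traj.append(ll)
            if len(traj) > 1 and abs(traj[-1] - traj[-2]) < tol * max(1.0, abs(traj[-2])):
                converged = True
                break
            S, sig2, W = self._em_updates(sol, C, sig2)
            if model == "DIAG":
                psi = np.clip(np.diag(S), _PSI_FLOOR * np.trace(S) / p, None)
            else:
                lam, psi = _fa_inner_em(S, lam, psi)

        Ge = np.diag(psi) if model == "DIAG" else lam @ lam.T + np.diag(psi)
        ll, sol, C = self._loglik_and_moments(Ge, sig2)
        traj.append(ll)
        W = sol[self.p:].reshape(self.p, self.r).T
        QL = self.Q * np.sqrt(self.gam)[None, :]
        U = QL @ W                               # n x p env-specific BLUPs
        out = {
            "model": model, "k": k, "tau": sol[:self.p], "sig2": sig2,
            "psi": psi, "lam": lam, "U": U, "W": W, "loglik": ll,
            "trajectory": traj, "converged": converged,
            "envs": self.envs, "ids": self.ids, "N": self.N,
        }
        if model == "FA":
            ge_inv = linalg.inv(Ge)
            out["scores"] = U @ ge_inv @ lam      # n x k conditional modes
        return out

    def _fit_mm(self, start, max_iter, tol):
        p, r = self.p, self.r
        y_all = np.concatenate([b["y"] for b in self.blocks])
        sig2 = np.array([0.6 * np.var(b["y"]) + 1e-3 for b in self.blocks])
        sg2 = 0.4 * np.var(y_all) + 1e-3
        if start is not None:
            sig2 = np.asarray(start.get("sig2", sig2), float).copy()
            sg2 = float(start.get("sg2", sg2))
        dim = p + r
        traj = []
        converged = False
        for _ in range(max_iter + 1):
            M = np.zeros((dim, dim))
            rhs = np.zeros(dim)
            for j, blk in enumerate(self.blocks):
                s = sig2[j]
                M[j, j] = blk["xbx"] / s
                M[j, p:] = blk["xbz"] / s
                M[p:, j] = blk["xbz"] / s
                M[p:, p:] += blk["zbz"] / s
                rhs[j] = blk["xby"] / s
                rhs[p:] += blk["zby"] / s
            M[p:, p:] += np.eye(r) / sg2
            cf = linalg.cho_factor(M, lower=True)
            sol = linalg.cho_solve(cf, rhs)
            C = linalg.cho_solve(cf, np.eye(dim))
            logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
            log_R = sum(blk["Nj"] * np.log(sig2[j]) + blk["logdetB"]
                        for j, blk in enumerate(self.blocks))
            ypy = sum(blk["yby"] / sig2[j] for j, blk in enumerate(self.blocks)) - rhs @ sol
            ll = -0.5 * ((self.N - p) * _LOG2PI + log_R + r * np.log(sg2) + logdet_M + ypy)
            traj.append(ll)
            if len(traj) > 1 and abs(traj[-1] - traj[-2]) < tol * max(1.0, abs(traj[-2])):
                converged = True
                break
            w = sol[p:]
            sg2 = max((w @ w + np.trace(C[p:, p:])) / r, _SIG_FLOOR)
            for j, blk in enumerate(self.blocks):
                e = blk["y"] - sol[j] - blk["Zt"] @ w
                quad = e @ blk["Binv"] @ e
                idxs = np.concatenate(([j], np.arange(p, dim)))
                Csub = C[np.ix_(idxs, idxs)]
                Wd = np.column_stack([np.ones(blk["Nj"]), blk["Zt"]])
                BiW = np.column_stack([blk["Bi_one"], blk["Bi_Z"]])
                sig2[j] = max((quad + float(np.sum(BiW * (Wd @ Csub)))) / blk["Nj"], _SIG_FLOOR)
        w = sol[p:]
        QL = self.Q * np.sqrt(self.gam)[None, :]
        u = QL @ w
        return {
            "model": "MM", "k": 0, "tau": sol[:p], "sig2": sig2, "sg2": sg2,
            "u_main": u, "U": np.tile(u[:, None], (1, p)), "loglik": ll,
            "trajectory": traj, "converged": converged,
            "envs": self.envs, "ids": self.ids, "N": self.N,
        }


# ---------------------------------------------------------------------------
# fast engine for complete designs
# ---------------------------------------------------------------------------

class BalancedEngine:
    """Direct REML for complete genotype x environment designs.

    Requires every genotype in every environment with a constant replicate
    count per environment and independent within-environment residuals.  The
    plot-level REML likelihood decomposes into within-cell contrasts plus a
    matrix-normal cell-mean model that is diagonalised by the eigenbasis of
    the genotype kernel.
    """

    def __init__(self, plots: pd.DataFrame, kernel_values: pd.DataFrame):
        ids = list(kernel_values.index)
        plots = plots[plots["genotype"].isin(ids)]
        cell = plots.groupby(["genotype", "environment"])["yield"]
        means = cell.mean().unstack()
        counts = cell.count().unstack()
        if means.isna().any().any():
            raise InputError("balanced engine requires a complete genotype x environment design")
        reps = counts.iloc[0]
        if not (counts.eq(reps, axis=1)).all().all():
            raise InputError("balanced engine requires constant replication within environment")
        self.envs = list(means.columns)
        self.ids = [g for g in ids if g in means.index]
        means = means.loc[self.ids]
        self.reps = reps[self.envs].to_numpy(float)
        self.Nj = (self.reps * len(self.ids)).astype(int)
        self.N = int(self.Nj.sum())
        self.p = len(self.envs)
        self.n = len(self.ids)
        ssw = (cell.apply(lambda s: ((s - s.mean()) ** 2).sum()).unstack()
               .loc[self.ids, self.envs].sum(axis=0))
        self.ssw = ssw.to_numpy(float)

        Gn = kernel_values.loc[self.ids, self.ids].to_numpy(float)
        w, V = np.linalg.eigh((Gn + Gn.T) / 2.0)
        self.gam = np.clip(w, 0.0, None)
        self.Q = V
        self.Ybar = means.to_numpy(float)
        self.Mstar = (self.Q.T @ self.Ybar) * np.sqrt(self.reps)[None, :]
        self.t = self.Q.T @ np.ones(self.n)

    # -- likelihood ----------------------------------------------------------
    def _loglik(self, Ge: np.ndarray, sig2: np.ndarray, want_blups: bool = False):
        p, n = self.p, self.n
        rh = np.sqrt(self.reps)
        ss = np.sqrt(sig2)
        A = (rh[:, None] * Ge * rh[None, :]) / (ss[:, None] * ss[None, :])
        a, Uv = np.linalg.eigh((A + A.T) / 2.0)
        a = np.clip(a, 0.0, None)
        D = self.gam[:, None] * a[None, :] + 1.0          # n x p
        W = (self.Mstar / ss[None, :]) @ Uv               # n x p
        h = np.sum(self.t[:, None] ** 2 / D, axis=0)
        g = np.sum(self.t[:, None] * W / D, axis=0)
        ypy_full = np.sum(W ** 2 / D)
        ypy = ypy_full - np.sum(g ** 2 / h)
        log_V = n * np.sum(np.log(sig2)) + np.sum(np.log(D))
        log_xvx = np.sum(np.log(self.reps / sig2)) + np.sum(np.log(h))
        dfw = self.Nj - n
        contrasts = np.sum(dfw * (_LOG2PI + np.log(sig2)) + self.ssw / sig2)
        ll = -0.5 * (contrasts + (n * p - p) * _LOG2PI + log_V + log_xvx + ypy)
        if not want_blups:
            return ll
        tau = (1.0 / rh) * ss * (Uv @ (g / h))
        resid = self.Mstar - np.outer(self.t, rh * tau)
        Rr = (resid / ss[None, :]) @ Uv
        back = ((Rr / D) @ Uv.T) / ss[None, :]
        Ut = self.gam[:, None] * ((back * rh[None, :]) @ Ge.T)
        U = self.Q @ Ut
        return ll, tau, U

    # -- parameter packing ---------------------------------------------------
    def _build(self, model, k, theta):
        p = self.p
        if model == "MM":
            sg2 = np.exp(theta[0])
            sig2 = np.exp(theta[1:1 + p])
            return np.full((p, p), sg2), sig2
        if model == "DIAG":
            psi = np.exp(theta[:p])
            sig2 = np.exp(theta[p:2 * p])
            return np.diag(psi), sig2
        lam = theta[:p * k].reshape(p, k)
        psi = np.exp(theta[p * k:p * k + p])
        sig2 = np.exp(theta[p * k + p:])
        return lam @ lam.T + np.diag(psi), sig2

    def fit(self, model: str, k: int = 0, start: dict | None = None,
            max_iter: int = 500, tol: float = 1e-9):
        p = self.p
        var_cols = np.var(self.Ybar, axis=0)
        sig0 = np.where(self.reps > 1, self.ssw / np.maximum(self.Nj - self.n, 1),
                        0.5 * var_cols + 1e-3)
        sig0 = np.maximum(sig0, 1e-4)
        if model == "MM":
            theta0 = np.concatenate([[np.log(np.mean(var_cols) / 2 + 1e-3)], np.log(sig0)])
        elif model == "DIAG":
            theta0 = np.concatenate([np.log(var_cols / 2 + 1e-3), np.log(sig0)])
        else:
            if start is not None and start.get("lam") is not None:
                lam0 = np.asarray(start["lam"], float)
                if lam0.shape[1] < k:
                    rng = np.random.default_rng(11 + k)
                    lam0 = np.column_stack(
                        [lam0, 0.05 * rng.standard_normal((p, k - lam0.shape[1]))])
                psi0 = np.asarray(start["psi"], float)
                sig0 = np.asarray(start.get("sig2", sig0), float)
            else:
                Sg = np.cov(self.Ybar.T) if p > 1 else np.atleast_2d(np.var(self.Ybar))
                w, V = np.linalg.eigh(Sg)
                lam0 = V[:, -k:] * np.sqrt(np.clip(w[-k:], 1e-4, None))[None, :]
                psi0 = np.clip(np.diag(Sg) - np.sum(lam0 ** 2, axis=1), 1e-3, None)
            theta0 = np.concatenate([lam0.ravel(), np.log(np.clip(psi0, 1e-6, None)),
                                     np.log(np.clip(sig0, 1e-8, None))])

        traj = []

        def nll(th):
            ge, sig2 = self._build(model, k, th)
            try:
                val = -self._loglik(ge, sig2)
                return val if np.isfinite(val) else 1e10
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e10

        def cb(th):
            traj.append(-nll(th))

        res = optimize.minimize(nll, theta0, method="L-BFGS-B", callback=cb,
                                options={"maxiter": max_iter, "ftol": tol})
        ge, sig2 = self._build(model, k, res.x)
        ll, tau, U = self._loglik(ge, sig2, want_blups=True)
        out = {
            "model": model, "k": k, "tau": tau, "sig2": sig2, "loglik": ll,
            "trajectory": traj or [ll], "converged": bool(res.success),
            "envs": self.envs, "ids": self.ids, "U": U, "N": self.N,
        }
        if model == "MM":
            out["sg2"] = float(np.exp(res.x[0]))
            out["u_main"] = U.mean(axis=1)
        elif model == "DIAG":
            out["psi"] = np.exp(res.x[:p])
        else:
            lam = res.x[:p * k].reshape(p, k)
            psi = np.exp(res.x[p * k:p * k + p])
            out["lam"], out["psi"] = lam, psi
            out["scores"] = U @ linalg.solve(ge + 1e-10 * np.eye(p), lam)
        return out


def dense_reml_loglik(plots: pd.DataFrame, kernel_values: pd.DataFrame,
                      Ge: np.ndarray, sig2, envs, b_shapes: dict | None = None) -> float:
    """Brute-force REML log-likelihood from the dense N x N covariance.

    Independent oracle used in tests: builds V = Z (Ge x Gn) Z' + R
    explicitly and evaluates the standard residual likelihood.
    """
    plots = plots.sort_values(["environment", "row", "col"], kind="mergesort").reset_index(drop=True)
    envs = list(envs)
    ids = [g for g in kernel_values.index if g in set(plots["genotype"])]
    gidx = {g: i for i, g in enumerate(ids)}
    eidx = {e: j for j, e in enumerate(envs)}
    Gn = kernel_values.loc[ids, ids].to_numpy(float)
    N = len(plots)
    p = len(envs)
    X = np.zeros((N, p))
    V = np.zeros((N, N))
    ge = np.asarray(Ge, float)
    sig2 = np.asarray(sig2, float)
    jj = plots["environment"].map(eidx).to_numpy()
    gg = plots["genotype"].map(gidx).to_numpy()
    X[np.arange(N), jj] = 1.0
    V = ge[np.ix_(jj, jj)] * Gn[np.ix_(gg, gg)]
    pos = 0
    for env in envs:
        sub = plots[plots["environment"] == env]
        Nj = len(sub)
        B = np.eye(Nj) if (b_shapes is None or env not in b_shapes) else np.asarray(b_shapes[env])
        V[pos:pos + Nj, pos:pos + Nj] += sig2[eidx[env]] * B
        pos += Nj
    y = plots["yield"].to_numpy(float)
    L = np.linalg.cholesky(V)
    logdetV = 2 * np.sum(np.log(np.diag(L)))
    Vi = linalg.cho_solve((L, True), np.eye(N))
    XtViX = X.T @ Vi @ X
    beta = linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    ypy = resid @ Vi @ resid
    return float(-0.5 * ((N - p) * _LOG2PI + logdetV + np.linalg.slogdet(XtViX)[1] + ypy))
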