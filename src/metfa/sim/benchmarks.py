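"""Compact planted-signal study designs for the bridge and forward stages.

These generators produce larger environment counts than the full plot-level
simulator can afford, by skipping the weather model and drawing ECs
directly.  They are used to measure second-stage predictive ability and
forward genomic-prediction gains under known signal strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..envirotyping import ECMatrix
from ..genetics import RelationshipMatrix
from ..rng import stream

__all__ = ["bridge_benchmark", "forward_benchmark"]


def bridge_benchmark(seed: int = 0, p: int = 60, w: int = 150, n_drivers: int = 5,
                     r2: float = 0.7):
    """EC matrix with a planted linear signal in the target.

    The target is a linear function of ``n_drivers`` ECs scaled so the
    population R^2 equals ``r2``; the remaining ECs are correlated nuisance
    (blocks of correlation ~0.5) as in real envirotyping matrices.  Returns
    (ECMatrix, target Series, driver EC names).
    """
    rng = stream(seed, "bridge-benchmark")
    envs = [f"E{i + 1:03d}" for i in range(p)]
    # real envirotyping matrices are strongly collinear: covariates of the
    # same kind across growth intervals share most of their variance
    block = 10
    rho = 0.9
    n_blocks = int(np.ceil(w / block))
    X = np.empty((p, w))
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, w)
        common = rng.normal(size=(p, 1))
        X[:, lo:hi] = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=(p, hi - lo))
    names = [f"EC{j + 1:03d}" for j in range(w)]
    # one driver per distinct block; one dominant driver plus secondary ones,
    # the way seasonal rainfall dominates yield main effects with soil and
    # temperature covariates contributing smaller terms
    driver_blocks = rng.choice(n_blocks, size=n_drivers, replace=False)
    drivers = [int(b * block + rng.integers(0, min(block, w - b * block)))
               for b in driver_blocks]
    base = np.array([1.6, 0.5, 0.45, 0.4, 0.35])
    coefs = (base[:n_drivers] if n_drivers <= base.size
             else np.concatenate([base, np.full(n_drivers - base.size, 0.35)]))
    coefs = coefs * rng.choice([-1, 1], n_drivers)
    signal = X[:, drivers] @ coefs
    signal = (signal - signal.mean()) / signal.std()
    noise = rng.normal(size=p)
    noise = (noise - noise.mean()) / noise.std()
    y = np.sqrt(r2) * signal + np.sqrt(1 - r2) * noise
    ec = ECMatrix(data=pd.DataFrame(X, index=envs, columns=names),
                  provenance=pd.Series("weather", index=names))
    target = pd.Series(y, index=envs, name="target")
    return ec, target, [names[d] for d in drivers]


def _family_kernel(rng, n_checks: int, n_cohort: int, m: int = 200, n_founders: int = 6):
    """Inbred-line kernel with family structure linking cohort to checks."""
    founders = rng.choice([-1.0, 1.0], size=(n_founders, m))
    ids = [f"CK{i + 1:02d}" for i in range(n_checks)] + \
          [f"NEW{i + 1:03d}" for i in range(n_cohort)]
    X = np.empty((len(ids), m))
    for i in range(len(ids)):
        f1, f2 = rng.choice(n_founders, size=2, replace=False)
        pick = rng.random(m) < 0.5
        X[i] = np.where(pick, founders[f1], founders[f2])
    pbar = (X.mean(axis=0) + 1) / 2
    c = 2 * np.sum(pbar * (1 - pbar))
    M = X + 1 - 2 * pbar
    G = M @ M.T / c + 1e-6 * np.eye(len(ids))
    kernel = RelationshipMatrix(pd.DataFrame(G, index=ids, columns=ids), kind="GRM")
    return kernel, ids[:n_checks], ids[n_checks:]


def forward_benchmark(seed: int = 0, gei: str = "strong", n_checks: int = 40,
                      n_cohort: int = 30, n_locations: int = 6,
                      train_years=(2020, 2021, 2022), test_year: int = 2023,
                      w: int = 25, resid_sd: float = 0.35):
    """MET with EC-driven GEI for forward cross-validation experiments.

    Check genotypes appear in every environment (two replicates); the cohort
    appears only in the test year.  With ``gei="strong"`` the two factor
    loadings are nearly deterministic functions of one EC each; with
    ``gei="none"`` the loadings are constant across environments, so genetic
    effects carry no genotype-by-environment interaction.

    Returns dict with plots, kernel, ec, env_table, tested/untested ids and
    the true structure.
    """
    rng = stream(seed, "forward-benchmark", gei)
    years = list(train_years) + [test_year]
    envs = [f"L{i + 1}_{y}" for y in years for i in range(n_locations)]
    p = len(envs)
    names = [f"EC{j + 1:03d}" for j in range(w)]
    X = rng.normal(size=(p, w))
    ec = ECMatrix(data=pd.DataFrame(X, index=envs, columns=names),
                  provenance=pd.Series("weather", index=names))

    if gei == "strong":
        lam1 = 0.75 + 0.10 * X[:, 0] + rng.normal(0, 0.03, p)
        lam2 = 0.55 * X[:, 1] / np.std(X[:, 1]) + rng.normal(0, 0.05, p)
    elif gei == "none":
        lam1 = np.full(p, 0.75)
        lam2 = np.zeros(p)
    else:
        raise ValueError("gei must be 'strong' or 'none'")
    lam = np.column_stack([lam1, lam2])
    psi = np.full(p, 0.02)
    main = 3.0 + 0.8 * X[:, 2] / np.std(X[:, 2]) + rng.normal(0, 0.2, p)

    kernel, checks, cohort = _family_kernel(rng, n_checks, n_cohort)
    ids = checks + cohort
    n = len(ids)
    Gn = kernel.values.to_numpy()
    L = np.linalg.cholesky(Gn)
    scores = L @ rng.normal(size=(n, 2))
    U = scores @ lam.T + (L @ rng.normal(size=(n, p))) * np.sqrt(psi)[None, :]

    rows = []
    for j, env in enumerate(envs):
        year = int(env.split("_")[1])
        present = checks + (cohort if year == test_year else [])
        slot = 0
        ncol = 10
        for g in present:
            gi = ids.index(g)
            for _ in range(2):
                r, c = slot // ncol + 1, slot % ncol + 1
                rows.append((env, year, env.split("_")[0], g, r, c,
                             main[j] + U[gi, j] + rng.normal(0, resid_sd)))
                slot += 1
    plots = pd.DataFrame(rows, columns=["environment", "year", "location",
                                        "genotype", "row", "col", "yield"])
    env_table = plots[["environment", "year"]].drop_duplicates().reset_index(drop=True)
    truth = {"lam": pd.DataFrame(lam, index=envs, columns=["fac1", "fac2"]),
             "main": pd.Series(main, index=envs), "psi": pd.Series(psi, index=envs),
             "scores": pd.DataFrame(scores, index=ids, columns=["fac1", "fac2"])}
    return {"plots": plots, "kernel": kernel, "ec": ec, "env_table": env_table,
            "tested": checks, "untested": cohort, "truth": truth,
            "test_year": test_year}
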