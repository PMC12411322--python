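"""End-to-end analysis pipeline on simulated data.

Chains every stage: simulate genotypes and the trial network, derive ECs,
build the genomic kernel, fit single-trial models, filter by reliability,
fit the DIAG/FA model ladder, rotate and summarise, bridge to ECs, predict
an extended grid and run forward cross-validation.  Used by the command-line
interface, the acceptance script and the end-to-end smoke test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import bridge as br
from .config import SimulationConfig
from .envirotyping import ECMatrix
from .famet import (assign_iclasses, build_b_shapes, fit_met_fa, fit_single_trial,
                    genetic_correlations, genotype_summaries, reliability_filter,
                    rotate_to_pc, variance_explained)
from .forward import compare_models, forward_folds, run_forward_cv
from .genetics import compute_grm, filter_markers, impute_markers, prune_markers
from .sim import (build_training_ecs, extended_ec_matrix, simulate_extended_grid,
                  simulate_genotypes, simulate_met)

__all__ = ["run_pipeline", "default_config"]


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def run_pipeline(config: SimulationConfig | None = None, seed: int = 0,
                 max_k: int = 2, n_grid_locations: int = 12,
                 run_forward: bool = True, stage2_methods=("RF",),
                 impute: bool = True, em_max_iter: int = 150) -> dict:
    """Run the full analysis; returns a dict of stage outputs."""
    if config is None:
        config = default_config(seed)
    elif seed:
        config = dataclasses.replace(config, seed=seed)
    out = {"config": config}

    # 1. genotypes -> kernel
    markers, pedigree = simulate_genotypes(config)
    if impute:
        markers, impute_report = impute_markers(markers, seed=config.seed)
        out["impute_report"] = impute_report
    markers = filter_markers(markers)
    markers, pruned = prune_markers(markers)
    kernel = compute_grm(markers)
    out.update(markers=markers, pedigree=pedigree, kernel=kernel, pruned_markers=pruned)

    # 2. envirotyping
    ec = build_training_ecs(config)
    out["ec"] = ec

    # 3. simulate the MET
    plots, truth = simulate_met(config, ec, kernel)
    out.update(plots=plots, truth=truth)

    # 4. single-trial models and reliability filter
    single_fits = []
    for env in ec.environments:
        sub = plots[plots["environment"] == env]
        single_fits.append(fit_single_trial(sub, environment=env))
    retained, excluded = reliability_filter(single_fits)
    out.update(single_fits=single_fits, retained=retained, excluded_envs=excluded)
    plots_kept = plots[plots["environment"].isin(retained)]
    ec_kept = ec.subset([e for e in ec.environments if e in retained])
    b_shapes = build_b_shapes([f for f in single_fits if f.environment in retained], plots)

    # 5. one-stage model ladder with warm starts
    fits = {"DIAG": fit_met_fa(plots_kept, kernel, k=0, b_shapes=b_shapes,
                               max_iter=em_max_iter)}
    prev = fits["DIAG"]
    for k in range(1, max_k + 1):
        fits[f"FA{k}"] = fit_met_fa(plots_kept, kernel, k=k, start=prev,
                                    b_shapes=b_shapes, max_iter=em_max_iter)
        prev = fits[f"FA{k}"]
    out["fits"] = fits
    best = rotate_to_pc(fits[f"FA{max_k}"])
    out["fit"] = best

    per_env, totals, vbar = variance_explained(best)
    corr = genetic_correlations(best)
    iclasses = assign_iclasses(best, corr)
    summaries = genotype_summaries(best, iclasses)
    out.update(variance_explained=per_env, variance_totals=totals, vbar=vbar,
               corr=corr, iclasses=iclasses, summaries=summaries)

    # 6. EC bridge: correlations + LOO CV + full-data stage-2 models
    targets = best.lam.copy()
    targets["main"] = best.main_effects
    out["ec_correlations"] = {
        t: br.correlate_ecs(ec_kept, targets[t], n_perm=200, seed=config.seed)
        for t in targets.columns}
    metrics, oof = br.loo_cv_stage2(ec_kept, targets, methods=stage2_methods,
                                    seed=config.seed)
    out.update(stage2_metrics=metrics, stage2_oof=oof)

    s2_models = {t: br.fit_stage2(ec_kept, targets[t], method="RF", seed=config.seed)
                 for t in targets.columns}
    main_adj = br.regression_adjuster(oof[("main", stage2_methods[0])], targets["main"])

    # 7. extended grid predictions + iClass probabilities
    grid = simulate_extended_grid(config, n_grid_locations, config.years)
    grid_ec = extended_ec_matrix(config, grid, ec)
    _, grid_table, grid_eblups = br.predict_extended(
        s2_models, grid_ec, fit=best, main_adjuster=main_adj)
    out.update(grid_ec=grid_ec, grid_predictions=grid_table,
               grid_eblups=grid_eblups,
               iclass_probabilities=br.iclass_probabilities(grid_table))

    # 8. forward cross-validation (latest year held out)
    if run_forward:
        env_table = (plots_kept[["environment", "year"]].drop_duplicates()
                     .reset_index(drop=True))
        cutoff = int(sorted(env_table["year"].unique())[-1])
        folds = forward_folds(env_table, [cutoff])
        cv = run_forward_cv(plots_kept, kernel, ec_kept, folds[0],
                            models=("MM", "DIAG", "FA1", "FA2"),
                            seed=config.seed, b_shapes=b_shapes,
                            met_kwargs={"max_iter": em_max_iter})
        out.update(forward_results=cv, forward_comparison=compare_models(cv))
    return out
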