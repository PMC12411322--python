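"""Result containers for the MET mixed-model stack."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InputError


@dataclass
class TrialStructure:
    """One candidate single-trial model structure."""

    row_effect: bool
    col_effect: bool
    resid_row: str  # id | ar1 | ar2
    resid_col: str

    def label(self) -> str:
        parts = []
        if self.row_effect:
            parts.append("row")
        if self.col_effect:
            parts.append("col")
        parts.append(f"{self.resid_row}(row):{self.resid_col}(col)")
        return "+".join(parts)


@dataclass
class SingleTrialFit:
    """Selected single-trial spatial model and its genotype estimates."""

    environment: str
    structure: TrialStructure
    variance_components: dict          # name -> estimate
    genotype_effects: pd.Series
    genotype_se: pd.Series
    sigma2_g: float
    pev: pd.Series
    reliability: pd.Series
    loglik: float
    aic: float
    mean_reliability: float
    n_candidates_converged: int = 0

    def __post_init__(self):
        if (self.pev < -1e-8).any():
            raise InputError("PEV must be >= 0")


@dataclass
class FAModelFit:
    """One-stage MET fit: MM, DIAG or reduced-rank FA_k with a kernel."""

    model: str                         # "MM" | "DIAG" | "FA1" | "FA2" | "FA3"
    kernel_kind: str                   # "GRM" | "COP" | "identity"
    environments: list
    genotype_ids: list
    main_effects: pd.Series            # fixed environment main effects
    lam: pd.DataFrame | None           # p x k loadings (None for MM/DIAG)
    d: np.ndarray | None               # k x k factor-score variances
    psi: pd.Series | None              # specific genetic variances
    sigma2_g: float | None             # MM-only genetic variance
    scores: pd.DataFrame | None        # n x k genotype scores
    env_effects: pd.DataFrame          # n x p genetic-effect BLUPs per environment
    resid_var: pd.Series               # per-environment residual scale
    loglik: float
    aic: float
    bic: float
    n_vparams: int
    converged: bool
    trajectory: list = field(default_factory=list)   # REML log-likelihood path
    rotated: bool = False
    negative_first_loading: list = field(default_factory=list)
    dropped_genotypes: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return 0 if self.lam is None else self.lam.shape[1]

    def ge(self) -> pd.DataFrame:
        """Between-environment genetic covariance Ge = Lam D Lam' + Psi."""
        if self.model == "MM":
            p = len(self.environments)
            ge = np.full((p, p), self.sigma2_g)
        elif self.lam is None:
            ge = np.diag(self.psi.to_numpy())
        else:
            lam = self.lam.to_numpy()
            d = self.d if self.d is not None else np.eye(lam.shape[1])
            ge = lam @ d @ lam.T + np.diag(self.psi.to_numpy())
        return pd.DataFrame(ge, index=self.environments, columns=self.environments)


@dataclass
class IClassAssignment:
    """Environment -> iClass strings over {p, n}^k, with the singleton-merge log."""

    classes: pd.Series
    merge_log: list                    # (environment, original, merged_into)

    def __post_init__(self):
        counts = self.classes.value_counts()
        if (counts == 1).any():
            raise InputError("iClass assignment left a singleton class after merging")


@dataclass
class GenotypeSummary:
    """Per-genotype adaptation summaries."""

    op: pd.Series                      # overall performance
    iclass_op: pd.DataFrame            # genotype x iClass
    rmsd: pd.Series                    # higher-order-factor stability index
    scores: pd.DataFrame
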