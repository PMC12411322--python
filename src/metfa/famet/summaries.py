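"""Genotype adaptation summaries and environment-specific EBLUPs.

Overall performance OP_i = mean first-factor loading x first-factor score;
iClassOP_{w,i} = sum_r (mean loading of factor r in class w) x score_{r,i};
the RMSD stability index is the root-mean-square over environments of the
higher-order-factor deviations sum_{r>=2} Lambda_{j,r} f_{r,i} - low RMSD
indicates broad adaptability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InputError
from .types import FAModelFit, GenotypeSummary, IClassAssignment

__all__ = ["genotype_summaries", "env_eblups"]


def genotype_summaries(fit: FAModelFit, iclasses: IClassAssignment) -> GenotypeSummary:
    if fit.lam is None or fit.scores is None:
        raise InputError("genotype summaries require an FA fit with scores")
    if not fit.rotated:
        raise InputError("genotype_summaries expects a rotated fit")
    lam = fit.lam.to_numpy(float)
    scores = fit.scores.to_numpy(float)
    p, k = lam.shape

    op = pd.Series(lam[:, 0].mean() * scores[:, 0], index=fit.genotype_ids)

    class_labels = sorted(iclasses.classes.unique())
    iclass_op = {}
    for w in class_labels:
        members = iclasses.classes.index[iclasses.classes == w]
        lam_bar = fit.lam.loc[members].mean(axis=0).to_numpy()
        iclass_op[w] = scores @ lam_bar
    iclass_op = pd.DataFrame(iclass_op, index=fit.genotype_ids)

    if k == 1:
        rmsd = pd.Series(0.0, index=fit.genotype_ids)
    else:
        dev = scores[:, 1:] @ lam[:, 1:].T        # n x p higher-order deviations
        rmsd = pd.Series(np.sqrt(np.mean(dev ** 2, axis=1)), index=fit.genotype_ids)

    return GenotypeSummary(op=op, iclass_op=iclass_op, rmsd=rmsd, scores=fit.scores)


def env_eblups(scores: pd.DataFrame, lam_new: pd.DataFrame,
               main_effects_new: pd.Series) -> pd.DataFrame:
    """Genotype x environment predictions for (possibly new) environments.

    prediction_{i,j} = main_j + sum_r Lambda_{j,r} f_{i,r}.  No
    environment-specific (Psi) contribution: it is unpredictable for new
    environments by construction.
    """
    if lam_new.shape[1] != scores.shape[1]:
        raise InputError(
            f"loading columns ({lam_new.shape[1]}) != score columns ({scores.shape[1]})")
    preds = scores.to_numpy(float) @ lam_new.to_numpy(float).T
    preds = preds + main_effects_new.reindex(lam_new.index).to_numpy(float)[None, :]
    return pd.DataFrame(preds, index=scores.index, columns=lam_new.index)
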