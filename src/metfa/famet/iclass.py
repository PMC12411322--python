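"""Interaction-class (iClass) environment typing.

Each environment's class string is the sign pattern of its rotated factor
loadings ('p' for non-negative, 'n' for negative), giving at most 2^k
classes with minimal genotype rank crossover within a class.  Classes
containing a single environment are iteratively merged into the class with
the highest mean genetic correlation to that environment.
"""

from __future__ import annotations

import pandas as pd

from ..errors import InputError
from .types import FAModelFit, IClassAssignment

__all__ = ["assign_iclasses", "iclass_string"]


def iclass_string(loadings) -> str:
    """Sign pattern of one environment's loadings (zero counts as 'p')."""
    return "".join("p" if v >= 0 else "n" for v in loadings)


def assign_iclasses(fit: FAModelFit, corr: pd.DataFrame) -> IClassAssignment:
    """Assign iClasses from loading signs and merge singleton classes."""
    if fit.lam is None or fit.k < 1:
        raise InputError("iClass assignment requires an FA fit with k >= 1")
    if not fit.rotated:
        raise InputError("assign_iclasses expects a rotated fit")
    classes = pd.Series(
        {env: iclass_string(fit.lam.loc[env].to_numpy()) for env in fit.environments})
    merge_log = []
    while True:
        counts = classes.value_counts()
        singles = counts.index[counts == 1]
        if len(singles) == 0 or counts.size == 1:
            break
        label = sorted(singles)[0]
        env = classes.index[classes == label][0]
        best, best_mean = None, -2.0
        for other in counts.index:
            if other == label:
                continue
            members = classes.index[classes == other]
            mean_r = float(corr.loc[env, members].mean())
            if mean_r > best_mean:
                best, best_mean = other, mean_r
        if best is None:
            break
        merge_log.append((env, label, best))
        classes.loc[env] = best
    return IClassAssignment(classes=classes, merge_log=merge_log)
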