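"""Synthetic marker panels and Purdy pedigrees via gene dropping.

Founders are fully inbred with block-correlated alleles (each block acts as a
small chromosome), so the panel carries realistic linkage disequilibrium for
the imputation and pruning steps.  Breeding lines descend from founder
crosses (single, three-way or backcross) followed by seven generations of
single-seed-descent selfing; backcrosses mate the recurrent parent to the F1
without inbreeding, matching the pedigree-expansion rules used downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..genetics import MarkerMatrix
from ..rng import stream

__all__ = ["simulate_genotypes", "check_ids", "cohort_of"]


def check_ids(config: SimulationConfig):
    return [f"CHECK{i + 1:02d}" for i in range(config.design.check_set_size)]


def cohort_of(config: SimulationConfig, line_id: str) -> int | None:
    """Year index of a cohort line (checks return None)."""
    if line_id.startswith("CHECK"):
        return None
    return int(line_id.split("_")[0][1:]) if line_id.startswith("Y") else None


def _founder_alleles(config: SimulationConfig, rng) -> np.ndarray:
    gc = config.genetics
    m, nb = gc.n_markers, gc.block_size
    n_blocks = int(np.ceil(m / nb))
    alleles = np.empty((gc.n_founders, m))
    rho = gc.block_corr
    for f in range(gc.n_founders):
        for b in range(n_blocks):
            lo, hi = b * nb, min((b + 1) * nb, m)
            z = rng.normal()
            x = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=hi - lo)
            alleles[f, lo:hi] = np.where(x > 0, 1.0, -1.0)
    return alleles


class _GeneDropper:
    """Meiosis with within-block linkage; blocks segregate independently."""

    def __init__(self, config: SimulationConfig, rng):
        self.m = config.genetics.n_markers
        self.nb = config.genetics.block_size
        self.r = config.genetics.recomb_rate
        self.rng = rng

    def gamete(self, hap1: np.ndarray, hap2: np.ndarray) -> np.ndarray:
        out = np.empty(self.m)
        for lo in range(0, self.m, self.nb):
            hi = min(lo + self.nb, self.m)
            cur = int(self.rng.integers(2))
            for j in range(lo, hi):
                if j > lo and self.rng.random() < self.r:
                    cur = 1 - cur
                out[j] = (hap1 if cur == 0 else hap2)[j]
        return out

    def cross(self, p1, p2):
        """(hap_from_p1, hap_from_p2) pair for the offspring."""
        return self.gamete(*p1), self.gamete(*p2)

    def self_n(self, ind, generations):
        for _ in range(generations):
            ind = (self.gamete(*ind), self.gamete(*ind))
        return ind


def simulate_genotypes(config: SimulationConfig):
    """Simulate the line panel: returns (MarkerMatrix, pedigree table).

    The pedigree table has columns id, purdy, selfing_generations; the Purdy
    strings round-trip through :func:`metfa.genetics.parse_purdy`.
    """
    gc = config.genetics
    rng = stream(config.seed, "genotypes")
    if gc.n_lines == 0:
        empty = MarkerMatrix(pd.DataFrame(dtype=float))
        return empty, pd.DataFrame(columns=["id", "purdy", "selfing_generations"])

    founders = _founder_alleles(config, rng)
    fnames = [f"F{i + 1}" for i in range(gc.n_founders)]
    dropper = _GeneDropper(config, rng)

    n_checks = min(config.design.check_set_size, gc.n_lines)
    n_cohort = gc.n_lines - n_checks
    years = config.years
    ids, purdys, genos = [], [], []

    def make_line(line_rng_key):
        lrng = stream(config.seed, "line", line_rng_key)
        dropper.rng = lrng
        u = lrng.random()
        f_idx = lrng.choice(gc.n_founders, size=3, replace=False)
        a, b, c = (founders[i] for i in f_idx)
        na, nbn, ncn = (fnames[i] for i in f_idx)
        if u < gc.backcross_fraction:      # backcross: A/B//A
            f1 = dropper.cross((a, a), (b, b))
            bc = dropper.cross(f1, (a, a))
            final, purdy = bc, f"{na}/{nbn}//{na}"
        elif u < gc.backcross_fraction + 0.25:  # three-way: A/B//C
            f1 = dropper.cross((a, a), (b, b))
            parent = dropper.self_n(f1, gc.selfing_generations)
            final, purdy = dropper.cross(parent, (c, c)), f"{na}/{nbn}//{ncn}"
        else:                               # single cross: A/B
            final, purdy = dropper.cross((a, a), (b, b)), f"{na}/{nbn}"
        line = dropper.self_n(final, gc.selfing_generations)
        return (line[0] + line[1]) / 2.0, purdy

    for i in range(n_checks):
        g, purdy = make_line(("check", i))
        ids.append(f"CHECK{i + 1:02d}")
        purdys.append(purdy)
        genos.append(g)
    for i in range(n_cohort):
        year = years[i % len(years)]
        g, purdy = make_line(("cohort", year, i))
        ids.append(f"Y{year}_{i + 1:03d}")
        purdys.append(purdy)
        genos.append(g)

    calls = pd.DataFrame(np.array(genos), index=ids,
                         columns=[f"M{j + 1:04d}" for j in range(gc.n_markers)])

    # missing calls: baseline rate everywhere, elevated on a marker subset
    mrng = stream(config.seed, "missing")
    mask = mrng.random(calls.shape) < gc.missing_rate
    n_high = int(round(gc.high_missing_markers * gc.n_markers))
    if n_high:
        high_cols = mrng.choice(gc.n_markers, size=n_high, replace=False)
        mask[:, high_cols] |= mrng.random((len(ids), n_high)) < gc.high_missing_rate
    vals = calls.to_numpy()
    vals[mask] = np.nan
    calls = pd.DataFrame(vals, index=calls.index, columns=calls.columns)

    pedigree = pd.DataFrame({
        "id": ids, "purdy": purdys,
        "selfing_generations": gc.selfing_generations,
    })
    return MarkerMatrix(calls), pedigree
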