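"""Genotype-side kernels: marker processing, GRM, pedigree kinship.

Marker calls are coded -1/0/+1 (0 = heterozygote) with NaN for missing; the
allele frequency ``p_s`` of a marker is the frequency of the +1 allele among
non-missing calls.  The genomic relationship matrix follows the
Endelman-Jannink formulation GRM = MM'/c with M = X + 1 - 2p and
c = 2 * sum_s p_s (1 - p_s).

Pedigrees arrive as Purdy-format cross strings ("A/B", "A/B//C", "A/B/3/D",
with "*" marking backcross doses).  Each individual is assumed to have been
selfed for seven generations before crossing, except backcrosses which mate
the recurrent parent to the F1 directly.  The expanded three-column pedigree
feeds a standard kinship (coefficient-of-parentage) recursion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError, PedigreeError
from .rng import substream_seed

__all__ = [
    "MarkerMatrix",
    "PedigreeTable",
    "RelationshipMatrix",
    "impute_markers",
    "filter_markers",
    "prune_markers",
    "compute_grm",
    "parse_purdy",
    "compute_cop",
    "SELFING_GENERATIONS",
]

SELFING_GENERATIONS = 7


@dataclass
class MarkerMatrix:
    """Genotype x marker call matrix, coded -1/0/+1 with NaN missing."""

    calls: pd.DataFrame

    def __post_init__(self):
        vals = self.calls.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise InputError("marker calls must be in {-1, 0, +1} or missing")
        self.calls = self.calls.astype(float)

    @property
    def genotypes(self):
        return list(self.calls.index)

    @property
    def markers(self):
        return list(self.calls.columns)

    def allele_freqs(self) -> pd.Series:
        """Frequency of the +1 allele per marker, from non-missing calls."""
        return (self.calls.mean(axis=0, skipna=True) + 1.0) / 2.0


@dataclass
class PedigreeTable:
    """Expanded three-column pedigree (id, p1, p2), parents before offspring."""

    table: pd.DataFrame

    def __post_init__(self):
        seen = set()
        for row in self.table.itertuples(index=False):
            for p in (row.p1, row.p2):
                if p is not None and p not in seen:
                    raise PedigreeError(f"parent '{p}' of '{row.id}' not defined earlier (cycle or disorder)")
            seen.add(row.id)

    @property
    def ids(self):
        return list(self.table["id"])


@dataclass
class RelationshipMatrix:
    """Symmetric n x n genotype kernel (GRM or COP)."""

    values: pd.DataFrame
    kind: str = "GRM"

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise InputError("relationship matrix must be symmetric")

    @property
    def ids(self):
        return list(self.values.index)

    def subset(self, ids) -> "RelationshipMatrix":
        ids = list(ids)
        return RelationshipMatrix(self.values.loc[ids, ids].copy(), self.kind)


# ---------------------------------------------------------------------------
# marker pipeline
# ---------------------------------------------------------------------------

def impute_markers(markers: MarkerMatrix, max_predictors: int = 500, maf_diff: float = 0.1,
                   oob_threshold: float = 0.2, n_trees: int = 200, seed: int = 0):
    """LD-based ensemble imputation of missing marker calls.

    For each focal marker with missing calls, up to ``max_predictors`` other
    markers with the greatest |correlation| to it (pairwise-complete, ties by
    marker order) and minor-allele-frequency difference < ``maf_diff`` are
    used as predictors of the categorical call in a random-forest classifier.
    Missing calls are imputed only when the forest's out-of-bag error is below
    ``oob_threshold``; otherwise the marker keeps its missing cells.

    Returns the (partially) imputed matrix and a per-marker report
    (oob_error, n_imputed, imputed flag).
    """
    calls = markers.calls.copy()
    X = calls.to_numpy(float)
    n, m = X.shape
    freqs = markers.allele_freqs().to_numpy()
    maf = np.minimum(freqs, 1 - freqs)
    col_means = np.nanmean(X, axis=0)
    Xfill = np.where(np.isnan(X), col_means, X)
    # pairwise-complete correlations approximated on mean-filled calls for
    # predictor ranking; the classifier itself is fit on observed rows only
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(Xfill, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)

    report = []
    cols = list(calls.columns)
    for j, name in enumerate(cols):
        miss = np.isnan(X[:, j])
        if not (~miss).any():
            report.append((name, np.nan, 0, False))
            continue
        if not miss.any():
            report.append((name, np.nan, 0, False))
            continue
        cand = np.where((np.abs(maf - maf[j]) < maf_diff) & (np.arange(m) != j))[0]
        if len(cand) == 0:
            report.append((name, np.nan, 0, False))
            continue
        order = cand[np.lexsort((cand, -np.abs(C[cand, j])))][:max_predictors]
        obs = ~miss
        y_obs = X[obs, j].astype(int)
        if len(np.unique(y_obs)) < 2 or obs.sum() < 10:
            report.append((name, np.nan, 0, False))
            continue
        rf_seed = int(substream_seed(seed, "impute", name).generate_state(1)[0] % (2**31))
        rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    random_state=rf_seed, n_jobs=1)
        rf.fit(Xfill[obs][:, order], y_obs)
        oob_error = 1.0 - rf.oob_score_
        if oob_error < oob_threshold:
            pred = rf.predict(Xfill[miss][:, order])
            calls.iloc[np.where(miss)[0], j] = pred.astype(float)
            report.append((name, oob_error, int(miss.sum()), True))
        else:
            report.append((name, oob_error, 0, False))

    rep = pd.DataFrame(report, columns=["marker", "oob_error", "n_imputed", "imputed"]).set_index("marker")
    return MarkerMatrix(calls), rep


def filter_markers(markers: MarkerMatrix, max_missing: float = 0.05,
                   min_maf: float = 0.025, max_het: float = 0.1) -> MarkerMatrix:
    """Marker QC: drop markers with > 5% missing, < 0.025 MAF or > 0.1 het calls.

    All three thresholds are strict inequalities (a marker at exactly the
    boundary is retained).
    """
    calls = markers.calls
    missing = calls.isna().mean(axis=0)
    freqs = markers.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    het = (calls == 0).mean(axis=0)
    keep = calls.columns[(missing <= max_missing) & (maf >= min_maf) & (het <= max_het)]
    if len(keep) == 0:
        raise InputError("all markers removed by QC filters")
    return MarkerMatrix(calls[keep].copy())


def prune_markers(markers: MarkerMatrix, r_threshold: float = 0.8):
    """Sequential LD pruning: scan markers in order; at each retained marker
    drop all not-yet-visited markers with |r| > ``r_threshold`` to it.

    The survivor set depends on scan order (input column order).  Returns the
    pruned matrix and the list of removed marker ids.
    """
    calls = markers.calls
    corr = calls.corr().to_numpy()  # pairwise-complete
    names = list(calls.columns)
    removed = set()
    m = len(names)
    for i in range(m):
        if names[i] in removed:
            continue
        for j in range(i + 1, m):
            if names[j] in removed:
                continue
            if abs(corr[i, j]) > r_threshold:
                removed.add(names[j])
    keep = [nm for nm in names if nm not in removed]
    return MarkerMatrix(calls[keep].copy()), sorted(removed)


def compute_grm(markers: MarkerMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix GRM = MM'/c (Endelman-Jannink scaling).

    M_ik = X_ik + 1 - 2 p_s with p_s estimated from the data and
    c = 2 * sum_s p_s (1 - p_s).  Residual missing calls are mean-imputed per
    marker before centring.  With sample-estimated frequencies every GRM row
    sums to zero.
    """
    X = markers.calls.to_numpy(float)
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means, X)
    p = (X.mean(axis=0) + 1.0) / 2.0
    c = 2.0 * np.sum(p * (1.0 - p))
    if c <= 0:
        raise InputError("monomorphic-only marker panel: c = 0, GRM undefined")
    M = X + 1.0 - 2.0 * p
    G = (M @ M.T) / c
    G = (G + G.T) / 2.0
    ids = markers.genotypes
    return RelationshipMatrix(pd.DataFrame(G, index=ids, columns=ids), kind="GRM")


# ---------------------------------------------------------------------------
# Purdy pedigree parsing and kinship
# ---------------------------------------------------------------------------

_SEP_RE = re.compile(r"/(\d+)/|//|/")


class _Node:
    __slots__ = ("name", "left", "right", "bc_parent", "bc_count")

    def __init__(self, name=None, left=None, right=None, bc_parent=None, bc_count=1):
        self.name = name
        self.left = left
        self.right = right
        self.bc_parent = bc_parent  # "left"/"right" when '*' marked
        self.bc_count = bc_count

    @property
    def is_founder(self):
        return self.name is not None

    def founders(self):
        if self.is_founder:
            return {self.name}
        return self.left.founders() | self.right.founders()


def _top_level_splits(s: str):
    """(position, depth, length) of each cross separator in s."""
    out = []
    for m in _SEP_RE.finditer(s):
        if m.group(1) is not None:
            depth = int(m.group(1))
        elif m.group(0) == "//":
            depth = 2
        else:
            depth = 1
        out.append((m.start(), depth, len(m.group(0))))
    return out


def _parse_node(s: str) -> _Node:
    s = s.strip()
    if not s:
        raise PedigreeError("empty parent in Purdy string")
    seps = _top_level_splits(s)
    if not seps:
        bc = re.fullmatch(r"(.+?)\*(\d+)", s) or re.fullmatch(r"(\d+)\*(.+)", s)
        if bc:
            raise PedigreeError(f"dangling backcross marker in '{s}'")
        return _Node(name=s)
    maxdepth = max(d for _, d, _ in seps)
    # split at the last occurrence of the highest-depth separator (left-assoc)
    pos, _, ln = [t for t in seps if t[1] == maxdepth][-1]
    left_s, right_s = s[:pos], s[pos + ln:]

    def strip_bc(txt):
        m = re.fullmatch(r"\s*(.*?)\*(\d+)\s*", txt)
        if m and not _top_level_splits(txt):
            return m.group(1), int(m.group(2))
        m = re.fullmatch(r"\s*(\d+)\*(.*?)\s*", txt)
        if m and not _top_level_splits(txt):
            return m.group(2), int(m.group(1))
        return txt, 1

    left_s, n_l = strip_bc(left_s)
    right_s, n_r = strip_bc(right_s)
    node = _Node(left=_parse_node(left_s), right=_parse_node(right_s))
    if n_l > 1:
        node.bc_parent, node.bc_count = "left", n_l
    elif n_r > 1:
        node.bc_parent, node.bc_count = "right", n_r
    return node


class _PedigreeBuilder:
    def __init__(self, selfing_generations=SELFING_GENERATIONS):
        self.rows = []  # (id, p1, p2)
        self.known = {}
        self.g = selfing_generations

    def add(self, iid, p1=None, p2=None):
        if iid not in self.known:
            self.rows.append((iid, p1, p2))
            self.known[iid] = (p1, p2)
        return iid

    def self_chain(self, base_id, generations, label=None):
        """Chain of single-seed-descent selfing individuals below base_id."""
        cur = base_id
        for gen in range(1, generations + 1):
            tag = f"{base_id}|S{gen}" if label is None else f"{base_id}|{label[:gen]}|S{gen}"
            self.add(tag, cur, cur)
            cur = tag
        return cur

    def realise(self, node: _Node, as_parent: bool) -> str:
        """Individual id usable as a crossing parent (or F1 if as_parent=False)."""
        if node.is_founder:
            return self.add(node.name)
        left_is_bc = node.bc_parent == "left"
        right_is_bc = node.bc_parent == "right"
        # implicit backcross: a pure-founder parent recurring in the other side
        if not (left_is_bc or right_is_bc):
            if node.right.is_founder and node.right.name in node.left.founders() and not node.left.is_founder:
                right_is_bc = True
            elif node.left.is_founder and node.left.name in node.right.founders() and not node.right.is_founder:
                left_is_bc = True

        def parent_of(child: _Node, mate_to_f1: bool) -> str:
            if child.is_founder:
                return self.add(child.name)
            f1 = self.realise(child, as_parent=False)
            if mate_to_f1:
                return f1  # backcross mates to the F1 without inbreeding
            return self.self_chain(f1, self.g)

        # a backcross on one side means the *other* side's F1 is mated directly
        p1 = parent_of(node.left, mate_to_f1=right_is_bc)
        p2 = parent_of(node.right, mate_to_f1=left_is_bc)
        f1_id = f"({p1}/{p2})"
        self.add(f1_id, p1, p2)
        # repeated backcross doses: mate the running F1 back to the recurrent parent
        doses = node.bc_count - 1
        recurrent = p1 if left_is_bc else p2
        for d in range(doses):
            nxt = f"({f1_id}BC{d + 1})"
            self.add(nxt, f1_id, recurrent)
            f1_id = nxt
        return f1_id


def parse_purdy(purdy_strings: dict, selection_histories: dict | None = None,
                selfing_generations: int = SELFING_GENERATIONS) -> PedigreeTable:
    """Expand Purdy cross strings into a three-column pedigree.

    ``purdy_strings`` maps line id -> Purdy string.  Each cross product is
    selfed ``selfing_generations`` times before being crossed again, except
    backcrosses (explicit "*" doses, or a recurrent founder reappearing) which
    mate to the F1 directly.  The named line descends from the final cross by
    the same number of selfing generations; lines from the same cross with
    selection histories share selfing-generation individuals up to the point
    their histories diverge.
    """
    b = _PedigreeBuilder(selfing_generations)
    histories = selection_histories or {}
    for iid, s in purdy_strings.items():
        if _unbalanced(s):
            raise PedigreeError(f"malformed Purdy string for '{iid}': '{s}'")
        node = _parse_node(s)
        if node.is_founder:
            b.add(iid, b.add(node.name), b.add(node.name))
            continue
        f1 = b.realise(node, as_parent=False)
        hist = histories.get(iid)
        label = None
        if hist:
            toks = re.split(r"[-/]", str(hist))
            label = tuple(toks[:selfing_generations])
            label = label + ("_",) * (selfing_generations - len(label))
        top = b.self_chain(f1, selfing_generations - 1, label=label)
        b.add(iid, top, top)
    df = pd.DataFrame(b.rows, columns=["id", "p1", "p2"])
    return PedigreeTable(df)


def _unbalanced(s: str) -> bool:
    """Leading/trailing separators or a bare '/ / /' run are malformed."""
    if re.search(r"/\s*$", s) or re.match(r"^\s*/", s):
        return True
    return bool(re.search(r"/\s*/\s*/", s.replace(" ", "")))


def compute_cop(pedigree: PedigreeTable, numerator: bool = False) -> RelationshipMatrix:
    """Coefficient-of-parentage (kinship) matrix from an expanded pedigree.

    Standard recursion on a parents-first ordering: phi(i,i) = (1 +
    phi(p1,p2))/2 and phi(i,j) = (phi(p1,j) + phi(p2,j))/2, with founders
    unrelated and non-inbred.  ``numerator=True`` returns the 2*phi numerator
    relationship view instead of raw kinship.
    """
    tab = pedigree.table
    ids = list(tab["id"])
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    p1 = [idx[p] if p is not None else -1 for p in tab["p1"]]
    p2 = [idx[p] if p is not None else -1 for p in tab["p2"]]
    for i in range(n):
        if p1[i] < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[p1[i], p2[i]])
        for j in range(i):
            if p1[i] < 0:
                phi[i, j] = phi[j, i] = 0.0
            else:
                phi[i, j] = phi[j, i] = 0.5 * (phi[p1[i], j] + phi[p2[i], j])
    if numerator:
        phi = 2.0 * phi
    return RelationshipMatrix(pd.DataFrame(phi, index=ids, columns=ids), kind="COP")
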