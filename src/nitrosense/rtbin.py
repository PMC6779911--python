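"""Response-type (RT) binning of coded expression patterns.

Coded patterns are clustered agglomeratively with one-minus-Pearson
distance and average (UPGMA) linkage, and the dendrogram is cut to a
fixed number of clusters.  Because thousands of genes share identical
coded patterns, the implementation clusters the *unique* patterns with
multiplicity weights; this is exactly equivalent to UPGMA on the full
gene set (duplicates merge first at height zero and thereafter act as a
single cluster whose size weights every average-linkage distance).

Zero-variance patterns (e.g. never differentially expressed) have no
defined Pearson correlation; by convention identical constant vectors
are at distance 0 and a constant vector is at distance 1 from anything
else, which groups non-responders together without asserting similarity
to responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design


@dataclass
class Dendrogram:
    """UPGMA merge tree in scipy linkage-matrix layout.

    ``merges`` has one row per merge: (node a, node b, height, new
    cluster size); leaves are 0..n-1 and merge i creates node n+i.
    """

    merges: np.ndarray
    n_leaves: int


def pattern_distance_matrix(patterns) -> np.ndarray:
    """One-minus-Pearson distance between pattern rows, in [0, 2].

    Constant rows follow the convention documented in the module
    docstring.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two patterns of equal length")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - corr
    if constant.any():
        # constant vs anything -> 1, unless the rows are identical -> 0
        d[constant, :] = 1.0
        d[:, constant] = 1.0
        const_idx = np.flatnonzero(constant)
        for i in const_idx:
            same = (x == x[i]).all(axis=1)
            d[i, same] = 0.0
            d[same, i] = 0.0
    np.fill_diagonal(d, 0.0)
    d[d < 1e-12] = 0.0  # snap rounding noise so duplicates merge at exactly 0
    return d


def average_linkage(dist: np.ndarray, sizes=None) -> Dendrogram:
    """UPGMA agglomeration of a full distance matrix.

    ``sizes`` gives initial cluster sizes (multiplicities of deduplicated
    items); inter-cluster distance is the size-weighted Lance-Williams
    average, i.e. the unweighted mean over all cross pairs of original
    items.  Ties in merge height are broken toward the lowest (i, j)
    index pair.
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("NaN distances")
    if n < 2:
        raise ValueError("need at least two items")
    sizes = np.ones(n) if sizes is None else np.asarray(sizes, dtype=float)
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    node_id = np.arange(n)
    cl_size = sizes.copy()
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)
        ii, jj = np.unravel_index(flat, sub.shape)
        act_idx = np.flatnonzero(active)
        i, j = act_idx[ii], act_idx[jj]
        if i > j:
            i, j = j, i
        h = work[i, j]
        ni, nj = cl_size[i], cl_size[j]
        merges[step] = (node_id[i], node_id[j], h, ni + nj)
        # Lance-Williams update into slot i
        new_row = (ni * work[i, :] + nj * work[j, :]) / (ni + nj)
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        cl_size[i] = ni + nj
        node_id[i] = n + step
    return Dendrogram(merges=merges, n_leaves=n)


def cut_to_k(dendro: Dendrogram, k: int) -> np.ndarray:
    """Cut the dendrogram into exactly k clusters by undoing the last
    k-1 merges.

    Returns integer labels 1..k; cluster ids are assigned in order of
    each cluster's first member index so the labeling is canonical.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        a, b, _, _ = dendro.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return labels


def assign_rts(patterns: pd.DataFrame, k: int = 201) -> pd.Series:
    """Cluster coded patterns into response types.

    Deduplicates patterns, runs weighted UPGMA, and cuts to
    ``min(k, n_unique)`` clusters (if fewer unique patterns exist than
    requested clusters, each pattern is its own RT).  Returns a gene ->
    RT id series; RT ids are numbered by first-member order, so the
    assignment is invariant to gene input order up to that canonical
    relabeling.
    """
    arr = patterns.to_numpy()
    uniq, inverse, counts = np.unique(
        arr, axis=0, return_inverse=True, return_counts=True
    )
    u = uniq.shape[0]
    k_eff = min(k, u)
    if u == 1:
        labels_u = np.array([1])
    else:
        dist = pattern_distance_matrix(uniq)
        dendro = average_linkage(dist, sizes=counts)
        labels_u = cut_to_k(dendro, k_eff)
    gene_labels = labels_u[inverse]
    # renumber by first appearance in gene order
    seen: dict[int, int] = {}
    out = np.empty(len(gene_labels), dtype=int)
    for i, lab in enumerate(gene_labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return pd.Series(out, index=patterns.index, name="rt")


def summarize_rts(cond_expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Mean standardized expression profile per RT over the 15 conditions.

    ``cond_expr`` is replicate-averaged expression (genes x conditions).
    Each gene is z-scored across conditions (constant genes contribute a
    zero profile); the RT profile is the member mean.  Adds
    ``n_members`` as a column.
    """
    expr = cond_expr.reindex(assignment.index)
    if expr.isna().any().any():
        raise ValueError("assignment covers genes absent from expression")
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 1e-12, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    prof = zdf.groupby(assignment).mean()
    prof["n_members"] = assignment.value_counts().reindex(prof.index)
    prof.index.name = "rt"
    return prof


def label_ns_rts(profiles: pd.DataFrame, margin: float = 0.0) -> pd.Series:
    """Flag RTs more highly expressed on nitrate than other N sources.

    An RT is nitrate-specific when its mean standardized expression over
    the early nitrate conditions (15 and 45 min) exceeds the
    corresponding ammonium, nitrite, and no-nitrogen means by more than
    ``margin``.
    """
    needed = [f"{t}_{tp}" for t in ("NO3", "NH4", "NO2", "noN") for tp in ("15min", "45min")]
    missing = [c for c in needed if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles missing conditions: {missing}")
    no3 = profiles[["NO3_15min", "NO3_45min"]].mean(axis=1)
    flags = pd.Series(True, index=profiles.index, name="ns_rt")
    for other in ("NH4", "NO2", "noN"):
        om = profiles[[f"{other}_15min", f"{other}_45min"]].mean(axis=1)
        flags &= no3 > om + margin
    return flags


def to_newick(dendro: Dendrogram, labels: list[str]) -> str:
    """Newick export of the merge tree with branch lengths from heights."""
    n = dendro.n_leaves
    height = {i: 0.0 for i in range(n)}
    text = {i: str(labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(dendro.merges):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node = n + step
        text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
        height[node] = h
    return text[2 * n - 2] + ";"
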