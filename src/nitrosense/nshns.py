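"""Nitrate-specificity (NS) scoring and the highly nitrate-sensitive set.

Candidate genes (expressed, and up on the nitrate pretreatment relative
to the starvation pretreatment) are scored along three contrasts on
replicate-averaged log2(RPKM+1):

* d1 — ammonium repression: nitrate pretreatment minus ammonium 15 min;
* d2 — nitrate induction vs ammonium: nitrate 15 min minus ammonium 15 min;
* d3 — nitrate induction vs nitrite: nitrate 15 min minus nitrite 15 min.

Each contrast is standardized over candidates; a gene is NS when it is
strictly above the chosen percentile (default 85th, linear-interpolation
definition) in all three dimensions, and HNS when it is NS and belongs
to a nitrate-specific response type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCALES = ("log2p1", "raw", "standardized_rpkm")


def candidate_filter(
    cond_expr: pd.DataFrame, min_rpkm: float = 5.0
) -> pd.Series:
    """Genes with mean RPKM above threshold and preNO3 > preN0.

    ``cond_expr`` is replicate-averaged RPKM per condition.  Both
    inequalities are strict.
    """
    for c in ("preN0", "preNO3"):
        if c not in cond_expr.columns:
            raise ValueError(f"missing pretreatment condition {c}")
    mean_ok = cond_expr.mean(axis=1) > min_rpkm
    pre_ok = cond_expr["preNO3"] > cond_expr["preN0"]
    return (mean_ok & pre_ok).rename("candidate")


def _transform(cond_expr: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "log2p1":
        return np.log2(cond_expr + 1.0)
    if scale == "raw":
        return cond_expr
    if scale == "standardized_rpkm":
        x = cond_expr.to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        z = np.where(sd > 1e-12, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return pd.DataFrame(z, index=cond_expr.index, columns=cond_expr.columns)
    raise ValueError(f"scale must be one of {SCALES}")


def ns_dimensions(
    cond_expr: pd.DataFrame,
    candidates: pd.Series,
    scale: str = "log2p1",
) -> pd.DataFrame:
    """Raw and standardized three-dimensional specificity contrasts.

    Returns a frame indexed by candidate genes with columns ``d1..d3``
    (simple subtraction on the chosen scale) and ``z1..z3``
    (standardized over candidates).
    """
    cand = candidates[candidates].index
    if len(cand) == 0:
        raise ValueError("no candidate genes")
    x = _transform(cond_expr.loc[cand], scale)
    d = pd.DataFrame(index=cand)
    d["d1"] = x["preNO3"] - x["NH4_15min"]
    d["d2"] = x["NO3_15min"] - x["NH4_15min"]
    d["d3"] = x["NO3_15min"] - x["NO2_15min"]
    for k in (1, 2, 3):
        col = d[f"d{k}"]
        sd = col.std(ddof=0)
        if sd < 1e-12:
            raise ValueError(f"degenerate input: dimension d{k} has zero variance")
        d[f"z{k}"] = (col - col.mean()) / sd
    return d


def ns_call(scores: pd.DataFrame, percentile: float = 85.0) -> pd.DataFrame:
    """NS membership: strictly above the percentile in all dimensions.

    Percentiles use the linear-interpolation (type 7) definition over
    candidates; ties at the threshold are excluded.  Adds ``pass1..3``,
    ``ns`` and the composite score (mean of z1..z3) to a copy of
    ``scores``.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be inside (0, 100)")
    out = scores.copy()
    for k in (1, 2, 3):
        thresh = np.percentile(out[f"z{k}"], percentile)
        out[f"pass{k}"] = out[f"z{k}"] > thresh
    out["ns"] = out["pass1"] & out["pass2"] & out["pass3"]
    out["composite"] = out[["z1", "z2", "z3"]].mean(axis=1)
    return out


def hns_intersect(ns_genes, ns_rt_members) -> set:
    """HNS = NS genes that also belong to a nitrate-specific RT."""
    return set(ns_genes) & set(ns_rt_members)


def score_table(
    cond_expr: pd.DataFrame,
    rt_assignment: pd.Series,
    ns_rt_flags: pd.Series,
    min_rpkm: float = 5.0,
    percentile: float = 85.0,
    scale: str = "log2p1",
) -> pd.DataFrame:
    """Full NS/HNS score table over all genes.

    Non-candidates carry NaN contrasts and False flags.  Returns one row
    per gene with candidacy, contrasts, pass flags, ns/hns membership
    and the composite score.
    """
    cand = candidate_filter(cond_expr, min_rpkm=min_rpkm)
    dims = ns_dimensions(cond_expr, cand, scale=scale)
    called = ns_call(dims, percentile=percentile)
    out = pd.DataFrame(index=cond_expr.index)
    out["candidate"] = cand
    for col in ("d1", "d2", "d3", "z1", "z2", "z3", "composite"):
        out[col] = called[col]
    for col in ("pass1", "pass2", "pass3", "ns"):
        out[col] = called[col].reindex(out.index, fill_value=False)
    ns_rts = set(ns_rt_flags[ns_rt_flags].index)
    in_ns_rt = rt_assignment.isin(ns_rts).reindex(out.index, fill_value=False)
    out["ns_rt_member"] = in_ns_rt
    out["hns"] = out["ns"] & out["ns_rt_member"]
    return out
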