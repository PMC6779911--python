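"""Peptide-to-protein rollup, normalization, clustering, and enrichment.

The rollup follows the reference-scaling scheme used for isobaric-label
proteomics: within each protein, the reference peptide is the one with
the fewest missing channels (ties broken by highest mean abundance);
every other peptide is shifted by the median difference to the
reference over shared observed channels, and the protein value per
channel is the median of the shifted peptides.  Peptides shared by
multiple proteins are rolled into protein-group rows and excluded from
enrichment by default.

Protein profiles are standardized first within treatment blocks and
then across the concatenated profile, clustered by k-means on the
z-scored rows (equivalent to one-minus-Pearson up to scale), and the
resulting proteome clusters (PCs) are surveyed for enrichment of
transcriptome response types with an upper-tail hypergeometric test and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .expression import bh_adjust


def rollup(peptides: pd.DataFrame, min_shared: int = 1) -> pd.DataFrame:
    """Roll a peptide table up one level (peptide -> protein).

    ``peptides`` must have ``peptide_id`` and ``protein_id`` columns;
    every remaining column is a log2 abundance channel (NaN = missing).
    Proteins listed with multiple parents (separated by ``;``) become
    protein-group rows flagged in the ``is_group`` column.  Peptides
    with no observed channel shared with the reference are dropped with
    a warning.
    """
    channels = [c for c in peptides.columns if c not in ("peptide_id", "protein_id")]
    if not channels:
        raise ValueError("peptide table has no abundance channels")
    rows = []
    for protein, grp in peptides.groupby("protein_id", sort=True):
        mat = grp[channels].to_numpy(dtype=float)
        n_missing = np.isnan(mat).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(mat, axis=1)
        # reference: most present, then most abundant
        order = np.lexsort((-means, n_missing))
        ref = mat[order[0]]
        shifted = [ref]
        for idx in order[1:]:
            pep = mat[idx]
            shared = ~np.isnan(ref) & ~np.isnan(pep)
            if shared.sum() < min_shared:
                warnings.warn(
                    f"peptide {grp['peptide_id'].iloc[idx]} shares no channel "
                    f"with the reference of {protein}; dropped"
                )
                continue
            shift = np.median((ref - pep)[shared])
            shifted.append(pep + shift)
        stacked = np.vstack(shifted)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            value = np.nanmedian(stacked, axis=0)
        rows.append(
            {
                "protein_id": protein,
                "n_peptides": stacked.shape[0],
                "is_group": ";" in str(protein),
                **dict(zip(channels, value)),
            }
        )
    out = pd.DataFrame(rows).set_index("protein_id")
    return out


def central_tendency_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median so every channel has median zero."""
    channels = [c for c in matrix.columns if c not in ("n_peptides", "is_group")]
    out = matrix.copy()
    for c in channels:
        med = out[c].median(skipna=True)
        if np.isnan(med):
            raise ValueError(f"sample {c} has no finite values")
        out[c] = out[c] - med
    return out


def standardize_two_stage(
    matrix: pd.DataFrame, treatment_blocks: dict[str, list[str]]
) -> pd.DataFrame:
    """Z-score each protein within treatment blocks, then across all.

    Blocks of size one cannot be scaled; they are centered only and the
    affected proteins flagged via an attribute ``singleton_blocks``.
    Zero-variance rows come back as all zeros.
    """
    channels = [c for block in treatment_blocks.values() for c in block]
    missing = [c for c in channels if c not in matrix.columns]
    if missing:
        raise ValueError(f"blocks reference unknown samples: {missing}")
    x = matrix[channels].to_numpy(dtype=float)
    out = np.empty_like(x)
    col_pos = {c: i for i, c in enumerate(channels)}
    singletons = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks allowed
        for name, block in treatment_blocks.items():
            idx = [col_pos[c] for c in block]
            sub = x[:, idx]
            mu = np.nanmean(sub, axis=1, keepdims=True)
            if len(idx) == 1:
                singletons.append(name)
                out[:, idx] = sub - mu
                continue
            sd = np.nanstd(sub, axis=1, ddof=0, keepdims=True)
            out[:, idx] = np.where(
                sd > 1e-12, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0
            )
        mu = np.nanmean(out, axis=1, keepdims=True)
        sd = np.nanstd(out, axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 1e-12, (out - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    res = pd.DataFrame(z, index=matrix.index, columns=channels)
    res.attrs["singleton_blocks"] = singletons
    return res


def cluster_pcs(matrix: pd.DataFrame, k: int = 100, seed: int = 0) -> pd.Series:
    """K-means proteome clusters on row-standardized profiles.

    On z-scored rows, Euclidean k-means is equivalent (up to scale) to
    one-minus-Pearson distance.  Rows containing NaN are dropped.
    Returns protein -> PC id (1..k).
    """
    clean = matrix.dropna(axis=0)
    if k > len(clean):
        raise ValueError(f"k={k} exceeds number of complete proteins ({len(clean)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(clean.to_numpy())
    return pd.Series(labels + 1, index=clean.index, name="pc")


def rt_pc_enrichment(rt: pd.Series, pc: pd.Series) -> pd.DataFrame:
    """Hypergeometric RT-by-PC overlap enrichment.

    The population is the set of genes with both an RT and a PC
    assignment (protein ids must be gene ids).  For each RT x PC pair
    with nonzero overlap the upper-tail probability P(X >= overlap) is
    computed and BH-adjusted across all tested pairs; ``fold`` is
    observed over expected overlap.
    """
    common = rt.index.intersection(pc.index)
    if len(common) == 0:
        raise ValueError("empty population: no genes with both assignments")
    rt_c = rt.loc[common]
    pc_c = pc.loc[common]
    m = len(common)
    rows = []
    rt_sizes = rt_c.value_counts()
    pc_sizes = pc_c.value_counts()
    cross = pd.crosstab(rt_c, pc_c)
    for rt_id in cross.index:
        for pc_id in cross.columns:
            overlap = int(cross.loc[rt_id, pc_id])
            n_rt = int(rt_sizes[rt_id])
            n_pc = int(pc_sizes[pc_id])
            p = float(hypergeom.sf(overlap - 1, m, n_rt, n_pc))
            expected = n_rt * n_pc / m
            rows.append(
                {
                    "rt": rt_id,
                    "pc": pc_id,
                    "overlap": overlap,
                    "population": m,
                    "rt_size": n_rt,
                    "pc_size": n_pc,
                    "pvalue": p,
                    "fold": overlap / expected if expected > 0 else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out.sort_values("pvalue", ignore_index=True)
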