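"""RPKM, negative-binomial exact differential expression, and coded patterns.

Each treatment-by-time group is tested against the ammonium pretreatment
with a conditional negative-binomial exact test (the classic exact test
for overdispersed count data): after total-count normalization, the sum
of each group's counts is negative binomial, and conditioning on the
grand total gives a discrete distribution over the possible splits that
is free of the unknown mean.  The two-sided p-value sums the
probabilities of all splits no more probable than the observed one.

Per-comparison p-values are Benjamini-Hochberg adjusted across genes and
converted to a coded pattern per gene: +1 significantly up, -1
significantly down, 0 otherwise, over the 12 ordered comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import design

PSEUDO = 0.5  # pseudo-count for fold-change of normalized means


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = 1e9 * c / (L * N) with gene length L in bp and library size N
    in mapped reads.  If ``library_sizes`` is omitted, column sums of the
    count matrix are used.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return 1e9 * counts.div(lengths, axis=0).div(library_sizes, axis=1)


def condition_means(rpkm: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged expression per condition (genes x 15 conditions)."""
    cond_of = metadata.set_index("sample_id")["condition"]
    grouped = rpkm.T.groupby(rpkm.columns.map(cond_of)).mean().T
    return grouped.reindex(columns=list(design.CONDITIONS))


# ---------------------------------------------------------------------------
# exact test


def _conditional_logpmf(t: int, r1: float, r2: float) -> np.ndarray:
    """log P(sum_A = x | sum_A + sum_B = t) for x = 0..t.

    sum_A ~ NB(r1, p), sum_B ~ NB(r2, p) independent with a shared
    success probability; conditioning on the total cancels p, leaving a
    negative hypergeometric form that depends only on (t, r1, r2).
    """
    x = np.arange(t + 1)
    lp = (
        gammaln(x + r1) - gammaln(x + 1)
        + gammaln(t - x + r2) - gammaln(t - x + 1)
    )
    lp -= lp.max()
    lp -= np.log(np.exp(lp).sum())
    return lp


def _binomial_logpmf(t: int, n1: int, n2: int) -> np.ndarray:
    """Poisson limit (dispersion -> 0): conditional split is binomial."""
    x = np.arange(t + 1)
    q = n1 / (n1 + n2)
    return (
        gammaln(t + 1) - gammaln(x + 1) - gammaln(t - x + 1)
        + x * np.log(q) + (t - x) * np.log1p(-q)
    )


def nb_exact_test(
    counts_a,
    counts_b,
    dispersion: float,
) -> tuple[float, float]:
    """Two-sided exact test of group B vs group A on normalized counts.

    Returns ``(log2fc, pvalue)`` where the fold change is of group B
    over group A means with a 0.5 pseudo-count.  Counts are assumed
    already library-size normalized (integers).  All-zero input in both
    groups is untestable: returns ``(0.0, 1.0)``.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one replicate")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    sa, sb = int(a.sum()), int(b.sum())
    t = sa + sb
    log2fc = float(np.log2((b.mean() + PSEUDO) / (a.mean() + PSEUDO)))
    if t == 0:
        return 0.0, 1.0
    if dispersion < 1e-10:
        lp = _binomial_logpmf(t, a.size, b.size)
    else:
        lp = _conditional_logpmf(t, a.size / dispersion, b.size / dispersion)
    pmf = np.exp(lp)
    pmf /= pmf.sum()
    p = float(pmf[pmf <= pmf[sa] * (1.0 + 1e-9)].sum())
    return log2fc, min(p, 1.0)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Total-count scaling to the mean library size, rounded to integers."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("empty library")
    factors = lib.mean() / lib
    return counts.mul(factors, axis=1).round().astype(np.int64)


def estimate_common_dispersion(counts: pd.DataFrame, metadata: pd.DataFrame) -> float:
    """Method-of-moments common dispersion across genes.

    For every gene and replicated condition, (s^2 - m) / m^2 estimates
    the squared biological coefficient of variation; the common value is
    the median over genes of the per-gene mean, floored at 1e-4.
    """
    norm = normalize_counts(counts).to_numpy(dtype=float)
    cond_of = metadata.set_index("sample_id")["condition"]
    groups = {}
    for j, s in enumerate(counts.columns):
        groups.setdefault(cond_of[s], []).append(j)
    ests = []
    for idx in groups.values():
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - m) / m**2
        phi[m <= 0] = np.nan
        ests.append(phi)
    if not ests:
        raise ValueError("no replicated conditions; cannot estimate dispersion")
    per_gene = np.nanmean(np.column_stack(ests), axis=1)
    common = float(np.nanmedian(per_gene))
    return max(common, 1e-4)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Exact-test DE of all 12 treatment-by-time groups vs the reference.

    Returns a long table with columns ``gene_id, comparison, log2fc,
    pvalue, fdr``; the BH family is genes within a comparison.  The
    dispersion defaults to the method-of-moments common estimate.
    """
    design.validate_metadata(metadata)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, metadata)
    norm = normalize_counts(counts)
    cond_of = metadata.set_index("sample_id")["condition"]
    cols_of: dict[str, list[str]] = {}
    for s in counts.columns:
        cols_of.setdefault(cond_of[s], []).append(s)
    ref = norm[cols_of[design.REFERENCE_CONDITION]].to_numpy()
    frames = []
    for comp in design.COMPARISONS:
        trt = norm[cols_of[comp]].to_numpy()
        n_genes = ref.shape[0]
        lfc = np.empty(n_genes)
        pval = np.empty(n_genes)
        for i in range(n_genes):
            lfc[i], pval[i] = nb_exact_test(ref[i], trt[i], dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.index,
                    "comparison": comp,
                    "log2fc": lfc,
                    "pvalue": pval,
                    "fdr": bh_adjust(pval),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def code_patterns(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Coded expression patterns: genes x 12 comparisons in {-1, 0, +1}.

    +1 iff fdr < alpha and log2fc > 0; -1 iff fdr < alpha and
    log2fc < 0; 0 otherwise.
    """
    fdr = de.pivot(index="gene_id", columns="comparison", values="fdr")
    lfc = de.pivot(index="gene_id", columns="comparison", values="log2fc")
    missing = [c for c in design.COMPARISONS if c not in fdr.columns]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    fdr = fdr[list(design.COMPARISONS)]
    lfc = lfc[list(design.COMPARISONS)]
    if fdr.isna().any().any():
        bad = fdr.index[fdr.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"genes with missing comparisons, e.g. {bad}")
    codes = np.where(
        fdr.to_numpy() < alpha, np.sign(lfc.to_numpy()).astype(int), 0
    ).astype(int)
    return pd.DataFrame(codes, index=fdr.index, columns=list(design.COMPARISONS))


def count_possible_patterns(n_comparisons: int, n_states: int = 3) -> int:
    """Number of distinct coded patterns: n_states ** n_comparisons."""
    if n_comparisons < 0 or n_states < 0:
        raise ValueError("counts must be nonnegative")
    return n_states**n_comparisons
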