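"""Promoter extraction and PWM scanning with exact score p-values.

Scanning mirrors the standard motif-occurrence workflow: every window
of promoter sequence (both strands) is scored with the log2-odds of the
position weight matrix against a 0-order background, and the p-value of
a score is the exact probability that a background-generated window
scores at least as high.  That null distribution is computed by dynamic
programming over the per-position score distribution after discretizing
scores to a fixed granularity (default 1e-3 bits); window scores use
the same discretization, so the reported p-values are exact for the
discretized scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
_ENC = {b: i for i, b in enumerate(BASES)}

DEFAULT_GRANULARITY = 1e-3  # bits


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T."""

    name: str
    probs: np.ndarray                      # (width, 4) row-stochastic
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probability matrix must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """log2-odds score matrix with a background-weighted pseudocount."""
        bg = self.background if background is None else np.asarray(background, float)
        if (bg <= 0).any():
            raise ValueError("background frequencies must be positive")
        bg = bg / bg.sum()
        adj = (self.probs + self.pseudocount * bg) / (1.0 + self.pseudocount)
        return np.log2(adj / bg)

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


def read_meme(path: str | Path) -> list[PWM]:
    """Parse PWMs from MEME minimal motif text format."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()])
            pwms.append(PWM(name=name, probs=np.array(rows), background=background.copy()))
            i += w
        i += 1
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_meme(pwms: list[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal motif text format."""
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = pwms[0].background
    out.append("Background letter frequencies")
    out.append(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)))
    out.append("")
    for pwm in pwms:
        out.append(f"MOTIF {pwm.name}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0"
        )
        for row in pwm.probs:
            out.append(" ".join(f"{x:.6f}" for x in row))
        out.append("")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# exact score distribution


def discretize_scores(
    score_matrix: np.ndarray, granularity: float = DEFAULT_GRANULARITY
) -> np.ndarray:
    """Integer score matrix: round(bits / granularity), per position/base."""
    return np.round(np.asarray(score_matrix) / granularity).astype(np.int64)


def score_distribution(
    int_scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, int]:
    """Exact pmf of the discretized window score under the background.

    Returns ``(pmf, offset)`` where ``pmf[k]`` is the probability of
    integer score ``k + offset``; built by convolving the per-position
    score distributions.
    """
    bg = np.asarray(background, float)
    bg = bg / bg.sum()
    lo = int(int_scores.min(axis=1).sum())
    hi = int(int_scores.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    pmf[0] = 1.0
    cur_lo = 0
    for pos in range(int_scores.shape[0]):
        new = np.zeros_like(pmf)
        base_min = int(int_scores[pos].min())
        for a in range(4):
            shift = int(int_scores[pos, a]) - base_min
            if bg[a] > 0:
                new[shift:] += pmf[: pmf.size - shift if shift else None] * bg[a]
        pmf = new
        cur_lo += base_min
    # cur_lo should equal lo by construction
    return pmf, cur_lo


def tail_pvalues(pmf: np.ndarray, offset: int) -> np.ndarray:
    """P(score >= k + offset) for every achievable integer score."""
    return np.cumsum(pmf[::-1])[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(b, -1) for b in seq.upper()], dtype=np.int64)


def estimate_background(promoters: dict[str, str]) -> np.ndarray:
    """0-order base frequencies over the promoter set (pseudocount 1)."""
    counts = np.ones(4)
    for seq in promoters.values():
        enc = _encode(seq)
        for a in range(4):
            counts[a] += int((enc == a).sum())
    return counts / counts.sum()


def scan(
    promoters: dict[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> pd.DataFrame:
    """Scan promoters on both strands; report windows with p <= threshold.

    The background defaults to the 0-order composition of the scanned
    promoter set.  Windows containing ambiguous bases are skipped.
    Returns columns ``gene_id, start, stop, strand, score, pvalue`` with
    0-based half-open coordinates on the forward strand.
    """
    if background is None:
        background = estimate_background(promoters)
    bg = np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")
    bg = bg / bg.sum()
    w = pwm.width

    fwd_int = discretize_scores(pwm.log_odds(bg), granularity)
    rc_int = discretize_scores(pwm.reverse_complement().log_odds(bg[::-1]), granularity)
    pmf, offset = score_distribution(fwd_int, bg)
    tails = tail_pvalues(pmf, offset)
    hi = offset + len(tails) - 1

    def pvalue_of(total: np.ndarray) -> np.ndarray:
        idx = np.clip(total, offset, hi) - offset
        p = tails[idx]
        p[total > hi] = tails[-1]
        return p

    records = []
    for gene, seq in promoters.items():
        enc = _encode(seq)
        n = len(enc) - w + 1
        if n <= 0:
            continue
        valid = np.ones(n, dtype=bool)
        bad = np.flatnonzero(enc < 0)
        for b in bad:
            valid[max(0, b - w + 1): b + 1] = False
        enc_safe = np.where(enc < 0, 0, enc)
        windows = np.lib.stride_tricks.sliding_window_view(enc_safe, w)
        for strand, mat in (("+", fwd_int), ("-", rc_int)):
            totals = mat[np.arange(w)[None, :], windows].sum(axis=1)
            pvals = pvalue_of(totals)
            keep = valid & (pvals <= p_threshold)
            for pos in np.flatnonzero(keep):
                records.append(
                    (
                        gene,
                        int(pos),
                        int(pos + w),
                        strand,
                        float(totals[pos] * granularity),
                        float(pvals[pos]),
                    )
                )
    return pd.DataFrame(
        records, columns=["gene_id", "start", "stop", "strand", "score", "pvalue"]
    )


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoters(
    genome: dict[str, str],
    coords: pd.DataFrame,
    length: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Upstream promoter sequences from gene coordinates.

    ``coords`` needs columns ``gene_id, contig, start, end, strand``
    with 0-based half-open coordinates.  For + strand genes the
    ``length`` bases ending immediately before ``start`` are returned;
    for - strand, the reverse complement of the bases following ``end``.
    Promoters truncated at contig edges keep whatever is available and
    are flagged.  Overlap with upstream genes is deliberately not
    truncated.
    """
    promoters: dict[str, str] = {}
    flags = []
    for row in coords.itertuples(index=False):
        if row.contig not in genome:
            raise ValueError(f"gene {row.gene_id}: contig {row.contig} not in genome")
        contig = genome[row.contig]
        if not 0 <= row.start <= row.end <= len(contig):
            raise ValueError(f"gene {row.gene_id} off contig {row.contig}")
        if row.strand == "+":
            lo = max(0, row.start - length)
            seq = contig[lo:row.start]
            truncated = row.start - length < 0
        elif row.strand == "-":
            hi = min(len(contig), row.end + length)
            seq = reverse_complement(contig[row.end:hi])
            truncated = row.end + length > len(contig)
        else:
            raise ValueError(f"gene {row.gene_id}: bad strand {row.strand!r}")
        promoters[row.gene_id] = seq
        flags.append({"gene_id": row.gene_id, "length": len(seq), "truncated": truncated})
    return promoters, pd.DataFrame(flags)


# ---------------------------------------------------------------------------
# density statistics


def density_stats(
    hits: pd.DataFrame,
    promoter_genes,
    gene_sets: dict[str, list],
    scores: pd.Series | None = None,
    focal: str | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> dict:
    """Motif abundance/density summary per gene set.

    For every set: fraction of promoters with at least one hit and mean
    hits per promoter.  Comparison sets larger than the focal set are
    summarized as the average over ``n_draws`` seeded random subsamples
    of the focal set's size.  If ``scores`` (a per-gene specificity
    score) is given, the Spearman correlation between per-gene hit count
    and score is reported.
    """
    universe = pd.Index(promoter_genes)
    hit_counts = (
        hits.groupby("gene_id").size().reindex(universe, fill_value=0)
        if len(hits)
        else pd.Series(0, index=universe)
    )
    rng = np.random.default_rng(seed)
    n_focal = len(gene_sets[focal]) if focal is not None else None
    per_set = {}
    for name, genes in gene_sets.items():
        genes = [g for g in genes if g in universe]
        if not genes:
            raise ValueError(f"gene set {name!r} empty within promoter universe")
        counts = hit_counts.loc[genes]
        if focal is not None and name != focal and len(genes) > n_focal:
            fracs, means = [], []
            for _ in range(n_draws):
                sub = rng.choice(genes, size=n_focal, replace=False)
                c = hit_counts.loc[sub]
                fracs.append((c > 0).mean())
                means.append(c.mean())
            per_set[name] = {
                "pct_with_hit": 100.0 * float(np.mean(fracs)),
                "mean_hits": float(np.mean(means)),
                "n": n_focal,
                "subsampled": True,
            }
        else:
            per_set[name] = {
                "pct_with_hit": 100.0 * float((counts > 0).mean()),
                "mean_hits": float(counts.mean()),
                "n": len(genes),
                "subsampled": False,
            }
    report = {"sets": per_set, "hit_counts": hit_counts}
    if scores is not None:
        common = universe.intersection(scores.dropna().index)
        rho, p = spearmanr(hit_counts.loc[common], scores.loc[common])
        report["spearman_rho"] = float(rho)
        report["spearman_p"] = float(p)
    return report
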