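"""Synthetic multi-omics data with planted ground truth.

Emulates a short-time nitrogen-response experiment on a diatom: bulk
RNA-seq counts over 15 conditions x 2 replicates, a partially observed
proteome correlated with the transcriptome, promoter sequences with
planted motif occurrences, exponential isotope-labeling curves, and a
small metabolite concentration table for flux constraints.

Genes are assigned one of five response archetypes:

* ``flat`` — no nitrogen response;
* ``n_replete`` — induced whenever a nitrogen source is present;
* ``n_deplete`` — induced under nitrogen starvation;
* ``nitrate_specific`` — induced on nitrate (including the nitrate
  pretreatment spike) and repressed on ammonium/nitrite;
* ``ammonium_specific`` — induced on ammonium.

Counts are negative binomial around the archetype mean profiles with
gene-level dispersions drawn log-normally around a common value, so the
downstream exact test's distributional assumption holds and its error
rates can be assessed against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design

ARCHETYPES = ("flat", "n_replete", "n_deplete", "nitrate_specific", "ammonium_specific")

DEFAULT_PROPORTIONS = {
    "flat": 0.475,
    "n_replete": 0.25,
    "n_deplete": 0.25,
    "nitrate_specific": 0.005,
    "ammonium_specific": 0.02,
}

#: metabolites reported in the labeling experiment
LABELED_METABOLITES = (
    "glutamate",
    "glutamine",
    "aspartate",
    "alanine",
    "ornithine",
    "arginine",
    "proline",
    "putrescine",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``effect_size_log2`` is the mean induction/repression magnitude of
    non-flat archetypes on the log2 scale; per-gene effects get a small
    Gaussian jitter but are clipped to at least three-quarters of the
    mean so planted responders stay well above the noise floor.
    """

    n_genes: int = 12_000
    n_replicates: int = 2
    archetype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_size_log2: float = 4.0
    nb_dispersion: float = 0.1
    library_size_mean: int = 500_000
    gene_length_range: tuple[int, int] = (500, 5000)
    baseline_log2_mean: float = 3.5
    baseline_log2_sd: float = 1.5
    responder_min_log2: float = 3.0
    proteome_detect_fraction: float = 0.517
    proteome_noise_sd: float = 0.5
    proteome_missing_rate: float = 0.2
    promoter_length: int = 500
    motif_rate_base: float = 0.2
    motif_rate_slope: float = 3.0
    labeling_k: float = 0.3
    labeling_timepoints: tuple[float, ...] = (0.0, 1.0, 3.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        props = self.archetype_proportions
        unknown = set(props) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")
        if any(p < 0 for p in props.values()):
            raise ConfigurationError("archetype proportions must be nonnegative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("archetype proportions must sum to 1")
        if not 0 <= self.proteome_detect_fraction <= 1:
            raise ConfigurationError("proteome_detect_fraction must be in [0,1]")
        for name in ("effect_size_log2", "nb_dispersion", "motif_rate_base",
                     "motif_rate_slope", "labeling_k", "proteome_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_genes and n_replicates must be positive")


@dataclass
class SyntheticDataset:
    """All pipeline inputs plus the planted truth table."""

    counts: pd.DataFrame          # genes x samples, integer counts
    metadata: pd.DataFrame        # one row per sample
    gene_lengths: pd.Series       # bp per gene
    peptides: pd.DataFrame        # peptide table, log2 abundance per sample
    promoters: dict[str, str]     # gene id -> promoter sequence (may be empty)
    labeling: pd.DataFrame        # metabolite labeling time series
    metabolite_conc: pd.DataFrame  # model metabolite concentrations at 0 and 1 h
    truth: pd.DataFrame           # per-gene archetype and effect size

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every table as TSV (promoters as FASTA); return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "metadata": outdir / "samples.tsv",
            "gene_lengths": outdir / "gene_lengths.tsv",
            "peptides": outdir / "peptides.tsv",
            "promoters": outdir / "promoters.fasta",
            "labeling": outdir / "labeling.tsv",
            "metabolite_conc": outdir / "metabolite_conc.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.gene_lengths.rename("length").to_csv(
            paths["gene_lengths"], sep="\t", index_label="gene_id"
        )
        self.peptides.to_csv(paths["peptides"], sep="\t", index=False)
        with open(paths["promoters"], "w") as fh:
            for gene, seq in self.promoters.items():
                fh.write(f">{gene}\n{seq}\n")
        self.labeling.to_csv(paths["labeling"], sep="\t", index=False)
        self.metabolite_conc.to_csv(paths["metabolite_conc"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# archetype mean profiles


def archetype_offsets(archetype: str, effect: float) -> np.ndarray:
    """log2 offset from baseline for each of the 15 conditions."""
    off = pd.Series(0.0, index=list(design.CONDITIONS))
    e = effect
    if archetype == "flat":
        pass
    elif archetype == "n_replete":
        for cond in design.CONDITIONS:
            if design.N_AVAILABLE[cond]:
                off[cond] = e
    elif archetype == "n_deplete":
        for cond in design.CONDITIONS:
            if not design.N_AVAILABLE[cond]:
                off[cond] = e
    elif archetype == "nitrate_specific":
        off["preNO3"] = e
        off["NO3_15min"] = e
        off["NO3_45min"] = e
        off["NO3_18h"] = e / 2
        for trt in ("NH4", "NO2"):
            for tp in design.TIMEPOINTS:
                off[f"{trt}_{tp}"] = -e / 2
    elif archetype == "ammonium_specific":
        off["preNH4"] = e
        off["NH4_15min"] = e
        off["NH4_45min"] = e
        off["NH4_18h"] = e / 2
    else:
        raise ConfigurationError(f"unknown archetype {archetype!r}")
    return off.to_numpy()


def _assign_archetypes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    props = np.array([config.archetype_proportions.get(a, 0.0) for a in ARCHETYPES])
    raw = props * config.n_genes
    counts = np.floor(raw).astype(int)
    remainder = config.n_genes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.array(ARCHETYPES, dtype=object), counts)
    rng.shuffle(labels)
    return labels


def generate_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset from a configuration.

    The seed in ``config`` fully determines the output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
    archetypes = _assign_archetypes(config, rng)

    # per-gene effect sizes: jittered but bounded away from zero
    effects = rng.normal(config.effect_size_log2, 0.25, size=n)
    effects = np.clip(effects, 0.75 * config.effect_size_log2, None)
    effects[archetypes == "flat"] = 0.0

    # specificity used for motif planting: >0 only for nitrate-specific genes
    spec = np.zeros(n)
    mask_no3 = archetypes == "nitrate_specific"
    if config.effect_size_log2 > 0:
        spec[mask_no3] = effects[mask_no3] / config.effect_size_log2
    else:
        spec[mask_no3] = 0.0

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    # Responder archetypes emulate genes the study could detect and score:
    # their baseline expression is floored at an expressed level, while
    # flat genes span the full (partly near-silent) expression range.
    base_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    responder = archetypes != "flat"
    base_log2[responder] = np.maximum(base_log2[responder], config.responder_min_log2)
    baseline_rpkm = 2.0**base_log2
    dispersions = config.nb_dispersion * np.exp(rng.normal(0.0, 0.3, size=n))

    meta = design.make_sample_metadata(config.n_replicates)
    n_samples = len(meta)
    lib_sizes = config.library_size_mean * np.exp(rng.normal(0.0, 0.1, n_samples))

    offsets = np.zeros((n, len(design.CONDITIONS)))
    for arch in ARCHETYPES:
        mask = archetypes == arch
        if not mask.any():
            continue
        for i in np.flatnonzero(mask):
            offsets[i] = archetype_offsets(arch, effects[i])

    cond_idx = np.array([list(design.CONDITIONS).index(c) for c in meta["condition"]])
    # expected counts: RPKM-scale baseline mapped back through length and depth
    mean_rpkm = baseline_rpkm[:, None] * 2.0 ** offsets[:, cond_idx]
    mu = mean_rpkm * lengths[:, None] * lib_sizes[None, :] / 1e9
    r = 1.0 / dispersions
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta["sample_id"].to_numpy())

    detected = rng.random(n) < config.proteome_detect_fraction
    peptides = _generate_peptides(
        counts_df, meta, genes, detected, config, rng
    )

    labeling = _generate_labeling(config, rng)
    metabolite_conc = _generate_metabolite_conc(rng)

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "archetype": archetypes,
            "effect_size": effects,
            "specificity": spec,
            "proteome_detected": detected,
            "planted_motif_count": np.full(n, -1),  # filled by generate_promoters
        }
    )

    return SyntheticDataset(
        counts=counts_df,
        metadata=meta,
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
        peptides=peptides,
        promoters={},
        labeling=labeling,
        metabolite_conc=metabolite_conc,
        truth=truth,
    )


def _generate_peptides(counts_df, meta, genes, detected, config, rng):
    """Peptide-level log2 abundances tracking each detected gene's transcript.

    The underlying protein profile is the gene's standardized log2 count
    profile plus Gaussian noise; 1-6 peptides per protein carry constant
    per-peptide offsets (to exercise reference scaling in the rollup) and
    a missing-at-random mask.
    """
    det_idx = np.flatnonzero(detected)
    samples = meta["sample_id"].to_numpy()
    rows = []
    log_counts = np.log2(counts_df.to_numpy() + 1.0)
    for i in det_idx:
        prof = log_counts[i]
        sd = prof.std()
        z = (prof - prof.mean()) / sd if sd > 0 else np.zeros_like(prof)
        protein = z + rng.normal(0.0, config.proteome_noise_sd, size=len(samples))
        n_pep = rng.integers(1, 7)
        for j in range(n_pep):
            offset = rng.normal(0.0, 2.0)
            vals = protein + offset + rng.normal(0.0, 0.2, size=len(samples))
            missing = rng.random(len(samples)) < config.proteome_missing_rate
            if missing.all():  # keep at least one observed channel
                missing[rng.integers(len(samples))] = False
            vals = np.where(missing, np.nan, vals)
            rows.append([f"{genes[i]}_pep{j + 1}", genes[i], *vals])
    cols = ["peptide_id", "protein_id", *samples]
    return pd.DataFrame(rows, columns=cols)


def _generate_labeling(config, rng):
    rows = []
    for met in LABELED_METABOLITES:
        k = config.labeling_k * np.exp(rng.normal(0.0, 0.4))
        pool = float(np.exp(rng.normal(4.0, 1.0)))
        series = generate_labeling_series(k, config.labeling_timepoints)
        for t, f in zip(series["time_h"], series["labeled_fraction"]):
            rows.append({"metabolite": met, "pool": pool, "time_h": t,
                         "labeled_fraction": f, "k_true": k})
    return pd.DataFrame(rows)


def _generate_metabolite_conc(rng):
    """Concentrations (nmol per mg protein) at 0 and 1 h for model sinks."""
    mets = ["pro_c", "glu_c", "gln_h", "asp_c", "ala_c"]
    base = np.exp(rng.normal(5.0, 0.5, len(mets)))
    delta = rng.normal(100.0, 50.0, len(mets))
    return pd.DataFrame({"metabolite": mets, "conc_0h": base, "conc_1h": base + delta})


# ---------------------------------------------------------------------------
# promoters


def generate_promoters(truth: pd.DataFrame, motif, config: SimulationConfig) -> dict[str, str]:
    """Plant motif consensus copies into random background promoters.

    The planted copy number per promoter is Poisson with rate
    ``motif_rate_base + motif_rate_slope * specificity(gene)``, so motif
    density rises with true nitrate specificity.  Planted counts are
    recorded in ``truth['planted_motif_count']`` (in place).
    """
    consensus = motif.consensus
    width = len(consensus)
    if width > config.promoter_length:
        raise ConfigurationError("motif wider than promoter")
    rng = np.random.default_rng(config.seed + 1)
    alphabet = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    counts = []
    for gene_id, spec_val in zip(truth["gene_id"], truth["specificity"]):
        lam = config.motif_rate_base + config.motif_rate_slope * spec_val
        n_plant = rng.poisson(lam)
        seq = alphabet[rng.integers(0, 4, size=config.promoter_length)]
        max_start = config.promoter_length - width
        for _ in range(n_plant):
            start = rng.integers(0, max_start + 1)
            seq[start:start + width] = list(consensus)
        promoters[gene_id] = "".join(seq)
        counts.append(int(n_plant))
    truth["planted_motif_count"] = counts
    return promoters


# ---------------------------------------------------------------------------
# labeling curves


def generate_labeling_series(
    k: float,
    timepoints,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential labeled-fraction curve f(t) = 1 - exp(-k t).

    Optional truncated-Gaussian noise keeps fractions inside [0, 1].
    """
    t = np.asarray(timepoints, dtype=float)
    if k < 0:
        raise ValueError("rate constant must be nonnegative")
    if (t < 0).any():
        raise ValueError("negative time")
    f = 1.0 - np.exp(-k * t)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        f = np.clip(f + rng.normal(0.0, noise_sd, size=t.shape), 0.0, 1.0)
    return pd.DataFrame({"time_h": t, "labeled_fraction": f})
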