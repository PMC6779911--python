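# Methods

This note documents the models, conventions, and numerical choices behind
`nitrosense`, stage by stage, including the decisions that were genuinely
open and the limitations a user should know about.

## Experimental design model

The package is organized around a fixed 15-condition layout: three
pretreatments (exponential growth on ammonium `preNH4`, nitrogen
starvation `preN0`, a nitrate spike `preNO3`) and four nitrogen
treatments (`noN`, `NH4`, `NO2`, `NO3`) sampled at 15 min, 45 min, and
18 h, usually with two biological replicates.  Differential expression is
always called against `preNH4`, giving 12 ordered comparisons.

Nitrogen availability is modeled per condition: the 300 µM treatment
doses are exhausted within a few hours, so every 18 h sample — including
the nominally nitrogen-fed treatments — is treated as nitrogen-deplete.
This matters twice: the `n_replete`/`n_deplete` synthetic archetypes
follow the availability flag, and it gives expression profiles temporal
structure *within* each treatment, which the proteome's within-treatment
standardization would otherwise erase.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with known truth:

* **Counts** are negative binomial around archetype mean profiles defined
  on the log2 RPKM scale.  Gene dispersions are log-normal
  (σ_log = 0.3) around a common `nb_dispersion` (default 0.1, a typical
  biological squared coefficient of variation for bulk RNA-seq), matching
  the exact test's model so its type-I error is assessable.
* **Archetypes** (`flat`, `n_replete`, `n_deplete`, `nitrate_specific`,
  `ammonium_specific`) get per-gene effect sizes jittered around
  `effect_size_log2` (default 4.0) and clipped at 75% of the mean.
  Nitrate-specific genes are induced on `preNO3` and the early nitrate
  samples, half-induced at NO3 18 h, and half-repressed on ammonium and
  nitrite — so all three specificity contrasts are positive by
  construction.  Default proportions plant 60 nitrate-specific genes in
  12,000 (0.5%), with half the genome responsive to overall N status.
* **Baseline expression** is log-normal (log2 RPKM ~ N(3.5, 1.5)).
  Responder archetypes are floored at log2 RPKM = 3: they model genes the
  study detected as responsive, which are by definition expressed;
  without the floor a fraction of "planted" responders would sit below
  the pipeline's own RPKM > 5 candidate filter and be unrecoverable by
  construction rather than by method failure.  Flat genes keep the full
  near-silent range.
* **Archetype allocation** is largest-remainder exact (counts match the
  configured proportions precisely), followed by a seeded shuffle.
* **Proteome**: a seeded random subset of genes (default fraction 0.517)
  is "detected"; the protein profile is the standardized transcript
  profile plus Gaussian noise (σ = 0.5), observed through 1-6 peptides
  per protein carrying constant offsets (σ = 2, to exercise reference
  scaling) and a 20% missing-at-random mask.
* **Promoters** are i.i.d. uniform ACGT with motif-consensus copies
  planted Poisson(λ_g), λ_g = `motif_rate_base` + `motif_rate_slope` ×
  specificity(g), specificity positive only for nitrate-specific genes.
* **Labeling** follows f(t) = 1 − e^(−kt) at t = 0, 1, 3, 8 h.

What the generator does **not** emulate: sequencing composition biases
(GC, length bias beyond the RPKM length term), correlated gene-gene
noise, batch effects, isoforms, peptide-level outliers, or real promoter
base composition.  Passing recovery tests therefore demonstrates internal
consistency of the method under its own assumptions, not performance on
real libraries.

## Differential expression and coding

Library-size normalization is total-count scaling to the mean depth,
rounded to integers (TMM is deliberately not reproduced; under extreme
asymmetric composition shifts total-count scaling is biased, which is a
documented simplification).  The common dispersion is a method-of-moments
estimate: per gene and replicated condition, (s² − m̄)/m̄² is averaged,
and the median over genes (floored at 1e-4) is used for every test.

The exact test conditions on the total of the two groups' (normalized)
counts.  With shared success probability the conditional split
distribution is negative-hypergeometric and depends only on the total and
the per-group shape parameters n/φ — not on the unknown mean — which also
makes the computation cacheable.  Two-sided p-values sum the
probabilities of all outcomes with probability ≤ (1 + 1e-9) × that of
the observed outcome.  For φ < 1e-10 the binomial limit is used
directly.  Fold changes are log2 of normalized group means with a 0.5
pseudo-count.  All-zero pairs are untestable and return (0, 1).

BH adjustment is per comparison across genes.  Coding uses strict
fdr < α (default 0.05) and the sign of the fold change.

## RT binning

Pattern distance is 1 − Pearson r.  Coded patterns are heavily
duplicated, so the implementation deduplicates patterns and runs
Lance-Williams UPGMA with multiplicity weights; this is exactly UPGMA on
the full gene set (duplicates merge at height 0 and then weight every
average).  Conventions and tie-breaks:

* zero-variance patterns: distance 0 to an identical constant pattern,
  1 to anything else (groups non-responders without asserting similarity
  to responders);
* distances below 1e-12 are snapped to 0 so duplicates merge exactly
  first; equal-height merges break toward the lowest index pair;
* `cut_to_k` undoes the last k−1 merges; RT ids are canonical by
  first-member order, so gene input order only relabels clusters;
* if fewer unique patterns than K exist, each pattern is its own RT.

K defaults to 201 and is an arbitrary, exposed knob.  An RT is flagged
nitrate-specific when its mean standardized profile over NO3 15/45 min
exceeds the corresponding ammonium, nitrite, and no-N means by more than
`margin` (default 0: any strict elevation counts; the declaring rule is a
documented convention since no canonical rule exists).

## NS / HNS scoring

Contrasts are computed on replicate-averaged log2(RPKM+1).  The scale is
a deliberate choice (`ns.scale` config also accepts `raw` and
`standardized_rpkm`): raw-RPKM subtraction is dominated by high
expressors.  Standardization is over candidates — the tested population —
not all genes.  Percentiles use the linear-interpolation (type 7)
definition with strict inequality, so exactly 15% of candidates pass per
dimension (±1 gene at ties).  The composite score for density
correlations is the mean of z1..z3.

## Proteome

Rollup formalizes "most present and most abundant" reference selection as
lexicographic (fewest missing channels, then highest mean).  Other
peptides shift by the median difference to the reference over shared
channels; peptides sharing no channel with the reference are dropped with
a warning.  Protein values are channel-wise medians including the
reference.  Shared peptides (protein ids joined by `;`) become
protein-group rows, excluded from enrichment.  Possible outlier-peptide
rejection in the original Inferno implementation is not modeled.

Two-stage standardization z-scores within treatment blocks and then
across the concatenation; singleton blocks are centered only and flagged.
Clustering is k-means (scikit-learn, n_init = 10, seeded) on the
standardized rows — on z-scored rows Euclidean distance is equivalent to
correlation distance up to scale.  Enrichment is upper-tail
hypergeometric per RT × PC pair with BH across all pairs; the test choice
is a documented convention.

## Motif scanning

PWMs are read/written in MEME minimal text format.  Scores are log2-odds
against a 0-order background (default: estimated from the scanned
promoter set) with a background-weighted pseudocount (0.01).  Scores are
discretized at 1e-3 bits; the null distribution of the discretized window
score is computed exactly by convolving per-position score distributions,
and a hit's p-value is the exact tail at its discretized score, so
reported p-values are exact for the discretized scores (the only
approximation is the 1e-3-bit rounding of per-position scores).  Both
strands are scanned; ambiguous-base windows are skipped; density is
reported per promoter (promoters are fixed-length, so per-kb differs by a
constant).  Larger comparison sets are summarized by seeded subsamples of
the focal set's size (100 draws, averaged).

The packaged motif (`hns_a_synthetic.meme`) is a synthetic stand-in with
an ETS-like CCGGAAG core, 85% dominant-base probability per position; it
is used for planting and scanning in synthetic runs, not a curated
biological motif.

## Flux model

The packaged network `ptoy_nitrogen` (48 metabolites, 59 reactions, four
compartments) is a hand-built, fully C/N-balanced caricature of diatom
nitrogen metabolism: chloroplast nitrate assimilation
(NR/NiR/GSII-GOGAT), mitochondrial urea assimilation (urease,
GSIII-GOGAT), split-organelle arginine synthesis (chloroplast ornithine,
mitochondrial carbamoyl-phosphate and citrulline, cytosolic ASS/ASL),
paired AST/ALT transaminases, and photosynthetic carbon supply.  The
fixture is deliberately engineered so the shuttle question is
identifiable: aspartate is only made in the chloroplast and consumed in
the mitochondrion, alanine the reverse; direct glutamate/glutamine
inter-organelle transport is capacity-limited (±0.01); the arginase
(catabolic) arm is closed because the simulations model only anabolic
growth.  Growth is carbon/O2-limited through the photosynthesis cap.

Run-time constraints: O2 evolution `EX_o2_e` ≤ 10 mmol gDW⁻¹ h⁻¹,
maintenance `AOX_m` ≥ 0.33 mmol gDW⁻¹ h⁻¹, ammonium organelle-cytosol
transport capped at ±0.1 mmol gDW⁻¹ h⁻¹ (the printed cap carries no time
unit; it is read as an hourly rate for dimensional consistency), and one
nitrogen exchange open per scenario.  Measured metabolite rates enter as
sinks with lb = ub = rate; concentrations in nmol (mg protein)⁻¹ convert
via a 70% protein fraction of biomass: rate = Δc × 0.7 × 10⁻³ mmol gDW⁻¹ h⁻¹.

LPs are solved with HiGHS (feasibility tolerance 1e-9; solution contracts
asserted at 1e-6).  Infeasible sink sets are relaxed by visiting sinks in
decreasing rate magnitude and bisecting the largest feasible scale (40
iterations).  The loopless pass fixes exchange/biomass/sink fluxes,
restricts each internal reaction to the direction it carried, and
minimizes internal |v|₁ — this preserves the objective exactly and cannot
increase internal flux.  Shuttle dominance is computed on the loopless
solution only (LP optima are degenerate) as each carrier route's share of
total inter-organelle amino-nitrogen (transporter flux × N atoms of the
carrier).

Limitations: absolute flux values are properties of the toy network, not
predictions for a real cell; no energy/redox currency is tracked (O2 acts
as the sole energetic proxy); thermodynamic and dynamic FBA are out of
scope.

## Labeling summaries

The labeling rate is 100 × f(t_ref)/t_ref percent per hour from a single
reference timepoint (default 3 h); on an exponential curve this equals
100(1 − e^(−3k))/3 and approaches 100k for small k with first-order error
≤ 3k/2 relative.  No natural-abundance correction is applied to labeled
fractions.  Composition percentages are shares of the total over the
measured metabolite set only.

## Problem sizes and determinism

Default analyses use 12,000 genes × 30 samples; clustering operates on
the deduplicated pattern set (typically a few hundred patterns).  The
test suite and the acceptance script use these defaults for end-to-end
recovery (several seeds) and smaller sizes for component oracles
(8-point UPGMA references, width ≤ 6 PWM enumerations, 5-channel peptide
tables); these sizes were chosen as the smallest at which each property
is meaningfully exercised.  All randomness flows through seeded
generators; a configuration plus seed reproduces outputs exactly.
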