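# nitrosense

Multi-omics analysis of short-time-course nitrogen responses in diatoms.

Diatoms thrive on episodic nitrate pulses in the ocean, and a small set of
genes — nitrate transporters, nitrate/nitrite reductases, the chloroplast
GS-GOGAT cycle, and candidate regulators — responds to nitrate within
minutes, distinctly from the response to ammonium, nitrite, or starvation.
`nitrosense` implements a complete, tested pipeline for identifying these
**highly nitrate-sensitive (HNS)** genes from a replicated pretreatment +
four-treatment x three-timepoint RNA-seq design, relating them to the
proteome, scanning their promoters for regulatory motifs, and simulating
the compartmentalized nitrogen fluxes that follow assimilation — together
with a synthetic-data generator that plants known ground truth so every
stage's error rates can be measured.

It is aimed at algal/plant molecular physiologists and computational
biologists who want either the full pipeline or its individual pieces
(exact-test DE coding, UPGMA pattern binning, percentile-gated specificity
scores, peptide rollup, FIMO-style PWM scanning with exact p-values,
metabolite-rate-constrained loopless FBA).

## Methods at a glance

**Coded expression patterns.** Expression is quantified as
RPKM = 10⁹·c/(L·N).  Each treatment x time group is tested against the
ammonium pretreatment with a conditional negative-binomial exact test:
after total-count normalization the conditional distribution of the group
split given the total is free of the unknown mean, and the two-sided
p-value sums all splits no more probable than the observed one
(dispersion → 0 recovers the binomial exact test).  After per-comparison
Benjamini-Hochberg adjustment each gene gets a code
cⱼ ∈ {−1, 0, +1} over the 12 comparisons (3¹² = 531,441 possible
patterns): +1 if fdr < 0.05 and log₂FC > 0, −1 if fdr < 0.05 and
log₂FC < 0, else 0.

**Response types (RTs).** Coded patterns are clustered agglomeratively
with distance d = 1 − Pearson r and average (UPGMA) linkage, and the
dendrogram is cut to K = 201 clusters.  RTs whose mean standardized
profile is higher on early nitrate than on ammonium, nitrite, and
starvation are flagged nitrate-specific.

**NS and HNS genes.** Candidates (mean RPKM > 5 and
RPKM(preNO₃) > RPKM(preN0)) are scored on replicate-averaged
log₂(RPKM+1) along three contrasts — ammonium repression
(d₁ = preNO₃ − NH₄·15min), nitrate-vs-ammonium induction
(d₂ = NO₃·15min − NH₄·15min), and nitrate-vs-nitrite induction
(d₃ = NO₃·15min − NO₂·15min) — each standardized over candidates.  A gene
is **NS** if it exceeds the 85th percentile in all three dimensions and
**HNS** if it is NS *and* belongs to a nitrate-specific RT.

**Proteome.** Peptides are rolled up to proteins by scaling to the most
present/most abundant reference peptide and taking channel-wise medians,
median-centered per sample, standardized within and then across
treatments, clustered by k-means into proteome clusters (PCs), and RT x PC
overlaps are tested with an upper-tail hypergeometric test (BH-adjusted).

**Promoter motifs.** 500 bp upstream regions are scanned on both strands
with a PWM's log₂-odds score; the p-value of a score is the exact tail
probability of the discretized score distribution under a 0-order
background, computed by dynamic programming.

**Flux.** A C/N-balanced toy compartmentalized network (extracellular,
cytosol, chloroplast, mitochondrion) is optimized for growth
(max v_bof subject to S·v = 0, lb ≤ v ≤ ub) with measured metabolite
pooling rates entering as fixed sinks (so S·v = dx/dt), an O₂ evolution
cap, a maintenance oxidase flux, and capped inter-compartment ammonium
transport.  A CycleFreeFlux-style pass fixes exchanges and the objective
and minimizes internal |v|₁, removing thermodynamically infeasible
cycles, before inter-organelle nitrogen shuttle usage (aspartate,
alanine, glutamate, glutamine routes) is reported.

## Worked example

```python
from nitrosense import PipelineConfig, SimulationConfig, run_all

cfg = PipelineConfig(sim=SimulationConfig(seed=1))  # 12,000 genes, 2 replicates
results = run_all(cfg, outdir="demo_out")

rec = results["recovery"]
print(f"HNS genes called: {rec['n_hns']} (planted nitrate-specific: {rec['n_planted']})")
print(f"precision={rec['hns_precision']:.3f} recall={rec['hns_recall']:.3f}")

density = results["motifs"]["density"]["sets"]
print(f"promoters with >=1 motif hit: HNS {density['HNS']['pct_with_hit']:.1f}% "
      f"vs background {density['background']['pct_with_hit']:.1f}%")

for scen, carrier in (("nitrate", "aspartate"), ("urea", "alanine")):
    rep = results["flux"][scen]["shuttle"]
    print(f"{scen} scenario: {carrier} shuttle dominance = "
          f"{rep['dominance'][carrier]:.2f}")
```

prints

```
HNS genes called: 62 (planted nitrate-specific: 60)
precision=0.968 recall=1.000
promoters with >=1 motif hit: HNS 95.2% vs background 23.0%
nitrate scenario: aspartate shuttle dominance = 0.96
urea scenario: alanine shuttle dominance = 0.96
```

The synthetic experiment plants 60 nitrate-specific genes among 12,000;
the pipeline recovers all of them with two false positives.  Planted
promoter motifs make HNS promoters far denser in hits than background
promoters, and the flux scenarios reproduce the qualitative shuttle
switch: nitrogen assimilated in the chloroplast (nitrate) leaves on an
oxaloacetate skeleton as aspartate, nitrogen assimilated in the
mitochondrion (urea) leaves on a pyruvate skeleton as alanine.

A CLI mirrors the library: `nitrosense simulate | de | code | rtbin |
hns | proteome | scan | flux | label | run-all | report`.

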