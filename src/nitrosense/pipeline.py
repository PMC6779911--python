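"""End-to-end orchestration of the analysis stages.

The pipeline runs, in dependency order: synthetic data generation (or
input loading), differential expression and pattern coding, response
type binning, NS/HNS scoring, proteome rollup/clustering/enrichment,
promoter motif scanning, flux balance scenarios, and labeling
summaries.  A manifest records parameters, seeds, and per-stage
outputs; identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, expression, flux, labeling, motifs, nshns, proteome, rtbin
from .synthetic import SimulationConfig, generate_experiment, generate_promoters

ALL_STAGES = ("transcriptome", "proteome", "motifs", "flux", "labeling")


@dataclass
class PipelineConfig:
    """Stage toggles and all stage parameters."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 0.05
    k_rt: int = 201
    k_pc: int = 100
    percentile: float = 85.0
    min_rpkm: float = 5.0
    rt_margin: float = 0.0
    ns_scale: str = "log2p1"
    p_threshold: float = 1e-4
    scenario: str = "nitrate"

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        sim = SimulationConfig(**doc.pop("sim", {}))
        return cls(sim=sim, **doc)


def packaged_motif() -> motifs.PWM:
    """The shipped synthetic nitrate-response promoter motif."""
    path = resources.files("nitrosense.data").joinpath("hns_a_synthetic.meme")
    with resources.as_file(path) as p:
        return motifs.read_meme(p)[0]


def run_transcriptome(dataset, cfg: PipelineConfig) -> dict:
    """DE coding, RT binning, and NS/HNS scoring on one dataset."""
    rpkm = expression.compute_rpkm(dataset.counts, dataset.gene_lengths)
    cond = expression.condition_means(rpkm, dataset.metadata)
    de = expression.de_table(dataset.counts, dataset.metadata)
    codes = expression.code_patterns(de, alpha=cfg.alpha)
    rt = rtbin.assign_rts(codes, k=cfg.k_rt)
    profiles = rtbin.summarize_rts(cond, rt)
    ns_rt = rtbin.label_ns_rts(
        profiles.drop(columns="n_members"), margin=cfg.rt_margin
    )
    scores = nshns.score_table(
        cond, rt, ns_rt,
        min_rpkm=cfg.min_rpkm, percentile=cfg.percentile, scale=cfg.ns_scale,
    )
    return {
        "rpkm": rpkm,
        "cond_expr": cond,
        "de": de,
        "codes": codes,
        "rt": rt,
        "rt_profiles": profiles,
        "ns_rt_flags": ns_rt,
        "scores": scores,
    }


def run_proteome(dataset, rt: pd.Series, cfg: PipelineConfig) -> dict:
    prot = proteome.rollup(dataset.peptides)
    norm = proteome.central_tendency_normalize(prot)
    channels = [c for c in norm.columns if c not in ("n_peptides", "is_group")]
    trt_of = dataset.metadata.set_index("sample_id")["treatment"]
    blocks: dict[str, list[str]] = {}
    for c in channels:
        blocks.setdefault(trt_of[c], []).append(c)
    std = proteome.standardize_two_stage(norm[channels], blocks)
    k = min(cfg.k_pc, len(std.dropna()))
    pc = proteome.cluster_pcs(std, k=k, seed=cfg.sim.seed)
    enrich = proteome.rt_pc_enrichment(rt, pc)
    return {"protein_matrix": norm, "standardized": std, "pc": pc, "enrichment": enrich}


def run_motifs(dataset, scores: pd.DataFrame, cfg: PipelineConfig) -> dict:
    pwm = packaged_motif()
    if not dataset.promoters:
        dataset.promoters.update(
            generate_promoters(dataset.truth, pwm, cfg.sim)
        )
    hits = motifs.scan(dataset.promoters, pwm, p_threshold=cfg.p_threshold)
    hns = scores.index[scores["hns"]].tolist()
    other = scores.index[~scores["hns"]].tolist()
    gene_sets = {"background": other}
    focal = None
    if hns:
        gene_sets["HNS"] = hns
        focal = "HNS"
    report = motifs.density_stats(
        hits,
        list(dataset.promoters),
        gene_sets,
        scores=scores["composite"],
        focal=focal,
        seed=cfg.sim.seed,
    )
    return {"pwm": pwm, "hits": hits, "density": report}


def run_flux(dataset, cfg: PipelineConfig) -> dict:
    model = flux.packaged_model()
    rates = flux.concentrations_to_rates(dataset.metabolite_conc)
    out = {}
    for scenario in ("nitrate", "urea"):
        constrained = flux.apply_constraints(model, rates, scenario=scenario)
        constrained, relaxations = flux.relax_to_feasible(constrained)
        sol = flux.loopless(constrained, flux.fba_optimize(constrained))
        out[scenario] = {
            "solution": sol,
            "relaxations": relaxations,
            "shuttle": flux.shuttle_report(sol),
        }
    return out


def run_labeling(dataset) -> dict:
    rates = labeling.labeling_rates(dataset.labeling)
    pools = dataset.labeling.groupby("metabolite")["pool"].first()
    return {"rates": rates, "composition": labeling.composition_percent(pools)}


def run_all(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages; optionally write outputs and manifest."""
    results: dict = {"config": cfg}
    manifest = {
        "parameters": {
            **{k: v for k, v in asdict(cfg).items() if k != "sim"},
            "sim": asdict(cfg.sim),
        },
        "stages": {},
    }
    dataset = generate_experiment(cfg.sim)
    results["dataset"] = dataset

    def _stage(name, fn, *args):
        t0 = time.perf_counter()
        results[name] = fn(*args)
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

    _stage("transcriptome", run_transcriptome, dataset, cfg)
    rt = results["transcriptome"]["rt"]
    scores = results["transcriptome"]["scores"]
    if "proteome" in cfg.stages:
        _stage("proteome", run_proteome, dataset, rt, cfg)
    if "motifs" in cfg.stages:
        _stage("motifs", run_motifs, dataset, scores, cfg)
    if "flux" in cfg.stages:
        _stage("flux", run_flux, dataset, cfg)
    if "labeling" in cfg.stages:
        _stage("labeling", run_labeling, dataset)
    results["recovery"] = recovery_report(scores, dataset.truth)
    manifest["recovery"] = results["recovery"]
    results["manifest"] = manifest

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dataset.write(outdir / "inputs")
        tr = results["transcriptome"]
        tr["de"].to_csv(outdir / "de.tsv", sep="\t", index=False)
        tr["codes"].to_csv(outdir / "coded_patterns.tsv", sep="\t")
        tr["rt"].to_csv(outdir / "rt_assignment.tsv", sep="\t")
        tr["rt_profiles"].to_csv(outdir / "rt_profiles.tsv", sep="\t")
        tr["scores"].to_csv(outdir / "ns_scores.tsv", sep="\t")
        pd.Series(sorted(scores.index[scores["hns"]])).to_csv(
            outdir / "hns_genes.txt", index=False, header=False
        )
        if "proteome" in results:
            results["proteome"]["pc"].to_csv(outdir / "pc_assignment.tsv", sep="\t")
            results["proteome"]["enrichment"].to_csv(
                outdir / "rt_pc_enrichment.tsv", sep="\t", index=False
            )
        if "motifs" in results:
            results["motifs"]["hits"].to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        if "flux" in results:
            for scen, res in results["flux"].items():
                res["solution"].fluxes.rename("flux").to_csv(
                    outdir / f"flux_{scen}.tsv", sep="\t"
                )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results


def recovery_report(scores: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Precision/recall of the HNS call against planted truth.

    The positive class is the planted nitrate-specific archetype; the
    confusion table counts archetypes among HNS and non-HNS genes.
    """
    if truth is None or len(truth) == 0:
        raise ValueError("no truth table available")
    truth = truth.set_index("gene_id")
    planted = set(truth.index[truth["archetype"] == "nitrate_specific"])
    called = set(scores.index[scores["hns"]])
    tp = len(called & planted)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    confusion = (
        pd.crosstab(truth["archetype"], scores["hns"].reindex(truth.index))
        .to_dict()
    )
    return {
        "hns_precision": precision,
        "hns_recall": recall,
        "n_hns": len(called),
        "n_planted": len(planted),
        "confusion": {str(k): v for k, v in confusion.items()},
    }
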