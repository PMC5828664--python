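"""End-to-end pipeline over a synthetic genome.

Runs simulate -> methylome -> chromatin states -> GWAS enrichment ->
fine-mapping -> overlap enrichment -> allelic imbalance in dependency
order, writing every stage artifact as TSV/BED into an output directory
together with a resolved-config record (seed, parameters) sufficient to
reproduce any artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelic, chromatin, enrichment, finemap, methylome, overlap, synthetic
from .io import write_bed, write_tsv


class PipelineConfig:
    """Resolved pipeline parameters; unknown keys are rejected."""

    _KNOWN = {
        "seed", "outdir", "sim", "min_coverage", "meth_cutoff", "fdr",
        "n_shuffles", "n_states", "n_restarts", "binarize_threshold_p",
        "meth_bin_cutoff", "k_snps", "credible_level", "ppa_threshold",
        "p_threshold", "n_perm", "min_ppa", "min_het", "min_depth",
        "min_per_allele",
    }

    def __init__(self, **kwargs):
        unknown = set(kwargs) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(kwargs.get("seed", 0))
        self.outdir = Path(kwargs.get("outdir", "pipeline_out"))
        sim_kwargs = dict(kwargs.get("sim", {}))
        sim_kwargs.setdefault("seed", self.seed)
        self.sim = synthetic.SimConfig(**sim_kwargs)
        self.min_coverage = int(kwargs.get("min_coverage", 10))
        self.meth_cutoff = float(kwargs.get("meth_cutoff", 0.5))
        self.fdr = float(kwargs.get("fdr", 0.05))
        self.n_shuffles = int(kwargs.get("n_shuffles", 100))
        self.n_states = int(kwargs.get("n_states", 8))
        self.n_restarts = int(kwargs.get("n_restarts", 3))
        self.binarize_threshold_p = float(kwargs.get("binarize_threshold_p", 1e-4))
        self.meth_bin_cutoff = float(kwargs.get("meth_bin_cutoff", 0.6))
        self.k_snps = int(kwargs.get("k_snps", 100))
        self.credible_level = float(kwargs.get("credible_level", 0.99))
        self.ppa_threshold = float(kwargs.get("ppa_threshold", 0.9))
        self.p_threshold = float(kwargs.get("p_threshold", 5e-8))
        self.n_perm = int(kwargs.get("n_perm", 1000))
        self.min_ppa = float(kwargs.get("min_ppa", 0.10))
        self.min_het = int(kwargs.get("min_het", 2))
        self.min_depth = int(kwargs.get("min_depth", 10))
        self.min_per_allele = int(kwargs.get("min_per_allele", 5))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved(self) -> dict:
        out = {k: v for k, v in vars(self).items() if k not in ("sim", "outdir")}
        out["outdir"] = str(self.outdir)
        out["sim"] = dataclasses.asdict(self.sim)
        return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages on the synthetic genome; returns the output dir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(config.resolved(), fh, indent=2, default=str)

    sim = config.sim

    # --- simulate + methylome ------------------------------------------------
    meth_table, meth_truth = synthetic.generate_methylome(sim)
    write_tsv(meth_table, out / "wgbs_counts.tsv")
    write_bed(meth_truth.umr_lmr_intervals, out / "truth_umr_lmr.bed")

    pooled = methylome.pool_samples(meth_table, min_coverage=config.min_coverage)
    write_tsv(pooled, out / "pooled_methylome.tsv")
    regions_meth = methylome.segment_hypomethylated(
        pooled, meth_cutoff=config.meth_cutoff, fdr=config.fdr,
        n_shuffles=config.n_shuffles, seed=config.seed)
    write_bed(regions_meth, out / "hypomethylated_regions.bed")

    # --- chromatin states ----------------------------------------------------
    truth = synthetic.generate_state_path(sim)
    counts, peaks = synthetic.generate_tracks(sim, truth)
    write_tsv(counts, out / "chip_counts.tsv")
    write_bed(peaks, out / "atac_peaks.bed")

    n_bins = sim.chrom_length // sim.bin_size
    seqs = []
    mark_names = sim.mark_names + ["ATAC", "hypometh"]
    for chrom in sim.chrom_names:
        sub = counts[counts["chrom"] == chrom]
        cols = [chromatin.binarize_chip(sub[m].to_numpy(),
                                        config.binarize_threshold_p)
                for m in sim.mark_names]
        cols.append(chromatin.binarize_atac(peaks, chrom, n_bins, sim.bin_size))
        cols.append(chromatin.binarize_methylation(
            pooled, chrom, n_bins, sim.bin_size, config.meth_bin_cutoff))
        seqs.append(np.column_stack(cols))
    model = chromatin.learn_model(seqs, n_states=config.n_states,
                                  n_restarts=config.n_restarts,
                                  seed=config.seed, mark_names=mark_names)
    model = chromatin.label_states(model)
    write_tsv(pd.DataFrame(model.emissions, columns=mark_names)
              .assign(label=model.labels), out / "state_emissions.tsv")
    write_tsv(pd.DataFrame(model.transitions), out / "state_transitions.tsv")

    state_beds = []
    for chrom, X in zip(sim.chrom_names, seqs):
        path, _ = chromatin.decode_states(model, X)
        state_beds.append(chromatin.states_to_bed(chrom, path, model.labels,
                                                  sim.bin_size))
    states_bed = pd.concat(state_beds, ignore_index=True)
    write_bed(states_bed, out / "chromatin_states.bed")

    # --- GWAS enrichment + fine-mapping -------------------------------------
    enhancer_states = states_bed[states_bed["name"].str.contains("enhancer")]
    annotations = {"enhancer": enhancer_states[["chrom", "start", "end"]]}
    if not sim.gamma_true:
        sim = dataclasses.replace(sim, gamma_true={"enhancer": 2.0})
    snps, gwas_truth = synthetic.generate_gwas(sim, annotations)
    write_tsv(snps, out / "gwas_summary.tsv")
    write_tsv(gwas_truth.causal_snp_per_region, out / "truth_causal_snps.tsv")

    regions = enrichment.segment_genome(snps, k=config.k_snps)
    single = enrichment.fit_single(regions, "enhancer")
    write_tsv(single.summary(), out / "enrichment_single.tsv")
    joint = enrichment.fit_joint(regions, ["enhancer"], seed=config.seed)
    write_tsv(joint.summary(), out / "enrichment_joint.tsv")

    ppa = finemap.snp_ppa(regions, joint)
    write_tsv(ppa, out / "snp_ppa.tsv")
    segs = finemap.significant_segments(ppa, config.ppa_threshold,
                                        config.p_threshold)
    write_tsv(segs, out / "significant_segments.tsv")
    flagged = segs.loc[segs["flagged"], "region_id"].tolist()
    sets = finemap.credible_sets_per_region(ppa, config.credible_level, flagged)
    if sets:
        cred = pd.concat([df.assign(region_id=rid) for rid, df in sets.items()],
                         ignore_index=True)
    else:
        cred = pd.DataFrame(columns=["region_id", "snp_id", "ppa",
                                     "ppa_norm", "cumulative_ppa"])
    write_tsv(cred, out / "credible_sets.tsv")

    # --- interval overlap enrichment -----------------------------------------
    lmrs = regions_meth[regions_meth["klass"] == "LMR"][["chrom", "start", "end"]]
    if len(lmrs) and len(enhancer_states):
        enr = overlap.permutation_enrichment(
            lmrs, enhancer_states, sim.chrom_sizes(),
            n_perm=config.n_perm, seed=config.seed,
            query_name="LMR", target_name="enhancer_states")
        write_tsv(pd.DataFrame([enr.__dict__]), out / "overlap_enrichment.tsv")

    # --- allelic imbalance ----------------------------------------------------
    ai_counts, ai_truth = synthetic.generate_allelic_counts(sim)
    write_tsv(ai_counts, out / "allele_counts.tsv")
    write_tsv(ai_truth.ai_variants, out / "truth_ai_variants.tsv")
    agg = allelic.aggregate_counts(ai_counts)
    agg["status"] = np.where(
        (agg["n_het_samples"] >= config.min_het)
        & (agg["ref_count"] + agg["alt_count"] >= config.min_depth)
        & (agg["ref_count"] >= config.min_per_allele)
        & (agg["alt_count"] >= config.min_per_allele),
        "eligible", "filtered")
    ai_results = allelic.test_allelic_imbalance(agg)
    write_tsv(ai_results, out / "allelic_imbalance.tsv")

    return out
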