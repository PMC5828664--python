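"""Compare credible sets from annotation-informed vs genetics-only PPAs."""

from isletepi import enrichment as enr
from isletepi import finemap as fm
from isletepi import synthetic as syn

cfg = syn.SimConfig(seed=4, n_regions=100, snps_per_region=100,
                    gamma_true={"enhancer": 3.5}, region_prior_true=0.5)
annots = {"enhancer": syn.annotation_intervals(cfg, 0.05)}
snps, _ = syn.generate_gwas(cfg, annots)
regions = enr.segment_genome(snps, k=100,
                             prior_variances=(cfg.abf_prior_variance,))

informed = enr.fit_single(regions, "enhancer", compute_ci=False)
baseline = enr.fit_null(regions)
ppa_i = fm.snp_ppa(regions, informed)
ppa_b = fm.snp_ppa(regions, baseline)

segs = fm.significant_segments(ppa_i)
print(f"{int(segs['flagged'].sum())} of {len(segs)} windows significant "
      "(regional PPA >= 0.9 or p < 5e-8)")

comp = fm.compare_models(ppa_i, ppa_b)
print(f"median 99% credible set: informed {comp['set_size_a'].median():.0f}"
      f" vs baseline {comp['set_size_b'].median():.0f} variants")
print(f"median top-variant PPA: informed {comp['top_ppa_a'].median():.3f}"
      f" vs baseline {comp['top_ppa_b'].median():.3f}")
# Enrichment-informed priors concentrate posterior mass: smaller credible
# sets and higher top-variant PPAs, the fine-mapping payoff of epigenomic
# annotation.
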