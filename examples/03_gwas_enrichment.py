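"""Estimate annotation enrichment from simulated GWAS summary statistics."""

from isletepi import enrichment as enr
from isletepi import synthetic as syn

cfg = syn.SimConfig(seed=3, n_regions=300, snps_per_region=100,
                    gamma_true={"enhancer": 2.0}, region_prior_true=0.3)
annots = {"enhancer": syn.annotation_intervals(cfg, 0.05)}
snps, _ = syn.generate_gwas(cfg, annots)

regions = enr.segment_genome(snps, k=100,
                             prior_variances=(cfg.abf_prior_variance,))
fit = enr.fit_single(regions, "enhancer")
print(f"planted gamma = 2.0 (log2FE {2.0 / enr.LN2:.2f})")
print(f"estimated log2FE = {fit.log2fe['enhancer']:.2f} "
      f"(95% CI {fit.ci_lo['enhancer']:.2f} to {fit.ci_hi['enhancer']:.2f})")
print(f"window prior Pi = {fit.region_prior:.3f} (planted 0.3); "
      f"significant: {fit.significant('enhancer')}")

null = enr.fit_null(regions)
stat, p = enr.lrt_nested(fit, null)
print(f"LRT vs annotation-free model: statistic {stat:.1f}, p = {p:.2e}")
# A lower CI bound above zero means the annotation is significantly
# enriched for GWAS signal; the LRT quantifies its contribution.
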