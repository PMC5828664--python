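"""Permutation overlap enrichment of called LMRs in planted enhancer bins."""

from isletepi import methylome as me
from isletepi import overlap as ov
from isletepi import synthetic as syn

cfg = syn.SimConfig(seed=5)
table, truth = syn.generate_methylome(cfg)
pooled = me.pool_samples(table)
regions = me.segment_hypomethylated(pooled, n_shuffles=50, seed=5)
lmrs = regions[regions["klass"] == "LMR"][["chrom", "start", "end"]]

# target: the planted hypomethylated intervals themselves
target = truth.umr_lmr_intervals[["chrom", "start", "end"]]
res = ov.permutation_enrichment(lmrs, target, cfg.chrom_sizes(),
                                n_perm=1000, seed=5,
                                query_name="called LMRs",
                                target_name="planted regions")
print(f"observed overlap: {res.observed:.0f} of {len(lmrs)} LMRs; "
      f"permuted mean {res.perm_mean:.2f}")
print(f"log2 fold enrichment = {res.log2fe:.2f}, "
      f"empirical p = {res.p_emp:.2e}")
# log2FE >> 0 with a floor-level p confirms the called LMRs sit where
# hypomethylation was planted, far beyond uniform-placement chance.
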