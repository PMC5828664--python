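# isletepi

Integrative epigenome annotation and GWAS fine-mapping for human
pancreatic islets — a tested, reusable re-implementation of the analysis
chain that links islet DNA methylation (WGBS), open chromatin (ATAC-seq)
and histone-mark ChIP-seq to type 2 diabetes (T2D) association signals.

It is written for statistical geneticists and computational biologists
who want to run, probe or extend each stage as a library call rather
than a collection of one-off tools:

- **Methylome**: pool per-sample WGBS counts (β = M/(M+U); array
  convention β = M/(M+U+100)), segment hypomethylated sequence into
  enhancer-like **LMRs** (<30 CpGs) and promoter-like **UMRs** at FDR
  0.05, and quantify how much fine-mapping posterior an assay's CpGs
  capture (±1 kb rule).
- **Chromatin states**: binarise tracks into 200 bp bins (Poisson upper
  tail for ChIP, ≥1 bp peak overlap for ATAC, β < 0.6 for
  hypomethylation) and fit a multivariate hidden Markov model with
  independent Bernoulli emissions (Baum–Welch, scaled forward–backward,
  posterior decoding), labelling enhancer subclasses as open /
  lowly-methylated / closed.
- **GWAS enrichment**: the hierarchical single-causal-variant window
  model — Wakefield approximate Bayes factors
  ln ABF = ½ln(V/(V+W)) + z²W/(2(V+W)), annotation-dependent causal
  priors softmax(γᵀxᵢ), window prior Π = logistic(κ), window likelihood
  L = (1−Π) + Π·Σᵢ πᵢ·ABFᵢ — with maximum-likelihood γ, profile 95% CIs,
  forward selection with a cross-validated L1 penalty, and nested-model
  likelihood-ratio tests. Enrichments are reported as log₂FE = γ/ln 2.
- **Fine-mapping**: reweighted per-SNP PPAs (Π·πᵢ·ABFᵢ/L), significant
  segments (regional PPA ≥ 0.9 or p < 5×10⁻⁸), minimal 99% credible
  sets, and model-vs-model credible-set comparisons.
- **Overlap enrichment**: permutation nulls (uniform within-chromosome
  shuffles, length preserved) with add-one empirical p and Bonferroni
  correction.
- **Allelic imbalance**: exact two-sided binomial tests of aggregated
  het-sample ATAC allele counts (≥2 hets, ≥10 reads, ≥5 per allele,
  PPA ≥ 0.10 in an enriched state), Benjamini–Hochberg FDR.

Because the human islet data are access-controlled, the package ships a
first-class synthetic-data generator (`isletepi.synthetic`) that plants
ground truth for every stage; all tests score the pipeline against that
truth. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Estimate annotation enrichment from simulated GWAS summary statistics
with a planted log-enrichment of 2 on a 5% annotation
(`examples/03_gwas_enrichment.py`):

```text
planted gamma = 2.0 (log2FE 2.89)
estimated log2FE = 2.09 (95% CI 0.41 to 3.46)
window prior Pi = 0.275 (planted 0.3); significant: True
LRT vs annotation-free model: statistic 5.5, p = 1.90e-02
```

The estimate recovers the planted enrichment (CI excludes zero, so the
annotation is called significantly enriched), the window prior Π matches
the planted 30% causal rate, and the likelihood-ratio test confirms the
annotation's contribution. Feeding that enrichment into fine-mapping
(`examples/04_finemapping_comparison.py`) shows the payoff:

```text
16 of 100 windows significant (regional PPA >= 0.9 or p < 5e-8)
median 99% credible set: informed 93 vs baseline 98 variants
median top-variant PPA: informed 0.311 vs baseline 0.160
```

Annotation-informed priors shrink 99% credible sets and roughly double
the posterior on the best variant — the qualitative behaviour that makes
epigenomic annotation useful for prioritising causal GWAS variants.
The other scripts in `examples/` demonstrate methylome segmentation,
chromatin-state learning, overlap enrichment, allelic-imbalance testing
and the end-to-end pipeline; each prints its results with a note on what
they mean. A thin CLI (`isletepi run|simulate|segment|overlap-enrich|ai-test`)
wraps the same calls for shell use.

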