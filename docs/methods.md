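# Methods

`isletepi` re-implements, as a tested library, an integrative analysis of
the human pancreatic islet epigenome against type 2 diabetes (T2D) GWAS
data: WGBS methylome segmentation, chromatin-state modelling over
binarised epigenomic tracks, hierarchical annotation enrichment of GWAS
summary statistics with Bayes-factor reweighted fine-mapping, permutation
overlap enrichment, and allele-specific chromatin accessibility testing.
Because the underlying human data are access-controlled, every stage is
exercised on synthetic data with planted ground truth; this note records
the models, the choices that were genuinely open, and what the synthetic
experiments do and do not establish.

## Methylome segmentation

Per-sample WGBS count tables (methylated reads M, unmethylated reads U
per CpG) are pooled by summing counts; CpGs with pooled coverage below
10X are dropped and beta = M/(M+U) is recomputed from pooled counts.
Array intensities use the convention beta = M/(M+U+100).

Hypomethylated regulatory regions are segmented with a deliberately
self-contained procedure (the published analyses delegate this step to an
external package whose algorithm we do not reproduce verbatim):

1. betas are smoothed with a centred running mean over 3 CpGs;
2. candidates are maximal runs of >= 4 consecutive CpGs with smoothed
   beta < 0.5;
3. each candidate is scored as sum(cutoff - beta) over its raw betas;
4. the null is the per-shuffle maximum candidate score over 100
   within-chromosome permutations of the betas (a max-statistic null —
   a shuffle with no candidate run contributes zero), giving add-one
   empirical p-values;
5. candidates passing Benjamini-Hochberg FDR 0.05 are classed LMR
   (< 30 CpGs) or UMR (otherwise).

A region with exactly 30 CpGs is classed UMR; the boundary is arbitrary
and documented. The max-statistic null is conservative for marginal
regions but has no trouble with biologically realistic hypomethylation
(planted regions at 85X pooled coverage are recovered with base-level
Jaccard ~0.95; smoothing trims at most a couple of edge CpGs, which is
why recall of very short LMRs is slightly below one). PMDs are consumed
as a caller-supplied exclusion mask, never detected.

## Chromatin states

Tracks are binarised into 200 bp bins: ChIP read counts by a Poisson
upper tail (present iff P(X >= count) < 1e-4 under the genome-wide mean
rate; the threshold follows the convention of the standard
chromatin-state tool and is exposed as a parameter), ATAC by >= 1 bp
peak overlap, and methylation by mean bin beta < 0.6 (a bin exactly at
0.6, or with no CpG, is not hypomethylated).

The state model is a hidden Markov model with independent Bernoulli
emissions per mark, fitted by Baum-Welch EM with per-position scaling
(posteriors stay finite for arbitrarily long sequences; chromosomes are
independent sequences sharing parameters). Initialisation perturbs
emissions around the mark marginal frequencies with a 0.5 diagonal boost
on transitions; 5 random restarts (seeded) keep the best final
log-likelihood. Decoding is posterior (forward-backward) with argmax
assignment. Because state identity is only defined up to permutation,
planted-recovery evaluations first match states by Hungarian assignment
on emission vectors.

States are labelled from their emission vectors (emission > 0.5 counts
as "has mark"), with enhancers subdivided by accessibility and
methylation: strong (H3K4me1+H3K27ac) and weak (H3K4me1 alone) enhancers
are each split into open (ATAC, hypomethylated), lowly-methylated
(closed, hypomethylated) and closed subclasses. Fitting two states to
i.i.d. data is non-identifiable (any split along the likelihood ridge is
maximum likelihood); the identifiable quantity — the stationary mixture
of emissions — reproduces the generating marginals, and that is what the
degenerate-case test asserts.

## GWAS enrichment and fine-mapping

The genome is partitioned into windows of k consecutive SNPs (k = 5000
for real GWAS; the synthetic experiments use k equal to the simulated
window size, stated with each result). Each window contains at most one
causal variant. With annotation memberships x_ik and enrichment
parameters gamma_k, the prior that SNP i is causal given its window is
softmax(sum_k gamma_k x_ik); the window prior is Pi = logistic(kappa).
Per-SNP evidence is the Wakefield approximate Bayes factor
ln ABF = 0.5 ln(V/(V+W)) + z^2 W / (2(V+W)), V = se^2, averaged
arithmetically over effect-size prior variances W in {0.01, 0.1, 0.5}
(case-control effects are log odds ratios; the form is identical). The
window likelihood L_r = (1-Pi) + Pi * sum_i softmax_i * ABF_i is
evaluated in log space with grouped logsumexp reductions.

(kappa, gamma) are estimated by L-BFGS-B; 95% CIs come from the profile
likelihood (bounds where the profile drops by chi2_1(0.95)/2 = 1.92,
re-optimising the other parameters), and an annotation is enriched when
the estimate and lower CI bound are above zero. Enrichments are internal
natural logs, reported as log2FE = gamma/ln 2, bounded at |log2FE| <= 20
with boundary hits flagged rather than reported as estimates. Joint
models are built by greedy forward selection on log-likelihood gain, an
L1 penalty chosen by 10-fold cross-validation over windows (grid
0/0.05/0.1/0.2/0.5, seeded fold assignment), and backward elimination
while the cross-validation likelihood improves. Nested models are
compared by 2*(lnL_full - lnL_reduced) against chi-square with df equal
to the annotation-count difference, on unpenalised likelihoods.

Reweighted per-SNP posteriors are PPA_i = Pi * softmax_i * ABF_i / L_r;
the regional PPA is their sum. Windows are significant when regional
PPA >= 0.9 or any SNP has p < 5e-8. 99% credible sets are the minimal
descending-PPA prefix reaching 0.99 after normalising by the regional
PPA (sets are conditional on the window containing a signal; the
convention is switchable), with leftmost-position tie-break.

## Interval overlap enrichment

Observed overlap (count of query intervals overlapping a target by
>= 1 bp; base-pair mode available) is compared with uniform
within-chromosome relocation of the query (lengths preserved, exclusion
mask honoured by rejection sampling). p = (1 + #{perm >= obs})/(n_perm+1)
(never zero at finite permutations), log2FE = log2(observed/permuted
mean), Bonferroni across the batch of targets actually tested (the batch
size is recorded in the output). Production analyses use 1e5
permutations; the test suite and acceptance script run at 1e3 with
correspondingly wider tolerances.

## Allelic imbalance

Candidate variants require reweighted PPA >= 0.10 and overlap with an
annotation retained in the joint enrichment model; testable variants
additionally require >= 2 heterozygous samples, aggregate depth >= 10
and >= 5 reads per allele (the per-allele rule subsumes the published
"at least nine reads" depth phrasing; both thresholds are parameters).
Aggregated reference counts are tested against p0 = 0.5 with the exact
two-sided binomial test (identical to R's binom.test; at p0 = 0.5 it
reduces to doubling the smaller tail, capped at 1), with BH FDR at 0.05.
Read-mapping bias removal requires an aligner and is outside this
package's contract: counts are assumed pre-filtered, and a
reference-bias-corrected null p0 != 0.5 can be supplied instead.

## Synthetic data: what it emulates and what it does not

The generator plants truth for every stage: a hypermethylated CpG
background (beta ~ U(0.80, 0.95)) carrying UMRs (35-80 CpGs,
beta ~ U(0.05, 0.20)) and LMRs (8-25 CpGs, beta ~ U(0.10, 0.40)) with
binomial read sampling at 10 samples x 8.5X (85X pooled, mirroring the
pooled design the package targets); a sticky Markov state path
(stay probability 0.95, quiescent state holding 90% of the genome so
individual regulatory states cover a realistic few percent) emitting
Poisson ChIP counts (30 signal / 5 background) and ATAC peaks; GWAS
windows with at-most-one causal SNP placed by the same softmax prior the
model assumes, effect ~ N(0, W), constant SE 0.03 (case-control scale)
and W = 0.01 by default (log-OR sd 0.1, i.e. odds ratios near 1.1,
typical of common T2D variants; the published analyses do not state
their effect-size prior, so it is exposed as a parameter); and
allele-specific counts over 17 samples with Hardy-Weinberg
heterozygosity at allele frequency 0.3, Poisson depth 18 per
heterozygous sample (aggregate ~130) and planted imbalance ratio 0.3.

Deliberately not emulated: linkage disequilibrium between SNPs (the
single-causal model does not require it), read-level sequence data,
diploid genomes, batch effects. The absence of LD matters for
interpretation: in real data, credible sets are large because many SNPs
share correlated evidence, and annotations shrink them by breaking those
ties; here, sets are large only when per-SNP evidence is weak. The
informative-prior fine-mapping experiment therefore uses a strong
planted enrichment (gamma = 3.5, comparable to the strongest
tissue-specific enhancer enrichments reported for islets) over windows
with region prior 0.5, where the effect on set sizes and top-variant
PPAs is systematic rather than tied to individual strong signals.
Passing tests show the estimators are correct and well calibrated under
the model's own assumptions — not that the pipeline is robust to LD,
mapping bias or population structure.

## Problem sizes and numerical choices

Planted-recovery experiments run at sizes chosen to make Monte-Carlo
error small relative to the tolerances they assert: 300 windows x 100
SNPs x 50 replicates for enrichment CI coverage; 100 windows (medians
over 50) for the fine-mapping comparison; 1e4 bins for HMM recovery; a
5 Mb genome (~50k CpGs) for segmentation; 50 replicates x 1000
permutations for null calibration; 1e4 replicates for binomial
calibration. Optimiser convergence is |delta lnL| < ~1e-9 relative
(L-BFGS-B ftol 1e-12); EM stops below tol 1e-4 or 200 iterations;
profile-CI roots are bracketed geometrically and solved by Brent to
1e-4. Degenerate inputs fail loudly: annotations covering no or all
SNPs, empty interval sets, zero-depth tests and unsorted methylomes all
raise instead of returning silent defaults.

## Known limitations

- The segmentation score null is conservative for regions barely below
  the cutoff; genuine biological hypomethylation is far from this regime.
- Profile CIs rely on chi-square asymptotics; at very small window
  counts (< ~100) coverage can drift a few points from nominal.
- The L1/CV joint-model selector inherits fgwas-style greediness: with
  strongly collinear annotations the selected set is data-dependent
  (the duplicate-annotation case is tested; general collinearity is not
  resolved, only penalised).
- `shuffle_intervals` rejection-samples against the exclusion mask and
  keeps the least-bad placement after 100 tries, which can very slightly
  under-disperse shuffles when the mask covers most of a chromosome.
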