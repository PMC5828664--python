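"""Synthetic islet multi-omic data with planted ground truth.

Every downstream stage of the package (methylome segmentation, chromatin
state learning, GWAS enrichment, fine-mapping, allelic imbalance) can be
exercised and scored against the planted truth emitted here, without any
external download. Generators are deterministic under a fixed seed: each
draws from its own :func:`numpy.random.default_rng` stream seeded from
``(config.seed, generator_offset)`` so that adding draws to one generator
never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import points_in_intervals

# per-generator offsets for the seed sequence (reproducibility without
# cross-generator coupling)
_OFF_METHYLOME = 1
_OFF_STATEPATH = 2
_OFF_TRACKS = 3
_OFF_GWAS = 4
_OFF_ALLELIC = 5
_OFF_ANNOT = 6


class InvalidConfigError(ValueError):
    pass


# canonical histone-mark order used by the default state plan
DEFAULT_MARKS = ("H3K4me1", "H3K27ac", "H3K4me3", "H3K36me3", "CTCF", "H3K27me3")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the study design the package emulates: 10 WGBS donors
    at 8.5X each (85X pooled), 17 ATAC donors, 200 bp bins, constant GWAS
    standard error 0.03 on the log-odds (case-control) scale.
    """

    genome_length: int = 5_000_000          # total bp across chromosomes
    n_chroms: int = 2
    cpg_density: float = 10.0               # CpGs per kb
    n_wgbs_samples: int = 10
    per_sample_coverage: float = 8.5        # mean reads per CpG per sample
    n_marks: int = 3                        # ChIP marks (H3K4me1, H3K27ac, H3K4me3, ...)
    bin_size: int = 200
    n_states_true: int = 6
    # methylome truth
    n_umr: int = 12
    n_lmr: int = 40
    # GWAS truth
    n_regions: int = 100
    snps_per_region: int = 100
    region_prior_true: float = 0.3          # Pi: P(region harbours a causal SNP)
    gamma_true: dict = field(default_factory=dict)  # annotation -> log-enrichment
    abf_prior_variance: float = 0.01        # W: causal effect-size prior variance
    gwas_se: float = 0.03                   # constant per-SNP standard error
    # allelic imbalance truth
    n_atac_samples: int = 17
    n_ai_variants: int = 20
    ai_ratio_true: float = 0.3              # planted ref-allele ratio at imbalanced sites
    ai_imbalanced_fraction: float = 0.15
    ai_allele_freq: float = 0.3
    ai_depth_per_sample: float = 18.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_chroms <= 0:
            raise InvalidConfigError("genome_length and n_chroms must be positive")
        if self.cpg_density <= 0 or self.per_sample_coverage <= 0:
            raise InvalidConfigError("cpg_density and per_sample_coverage must be positive")
        if not (0.0 <= self.region_prior_true <= 1.0):
            raise InvalidConfigError("region_prior_true must lie in [0, 1]")
        if not (0.0 < self.ai_ratio_true < 1.0):
            raise InvalidConfigError("ai_ratio_true must lie in (0, 1)")
        if self.n_wgbs_samples <= 0 or self.n_atac_samples <= 0:
            raise InvalidConfigError("sample counts must be positive")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chroms

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def mark_names(self) -> list[str]:
        return list(DEFAULT_MARKS[: self.n_marks])

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, offset])


@dataclass
class TruthSet:
    """Planted ground truth accompanying each simulated dataset."""

    umr_lmr_intervals: pd.DataFrame | None = None   # chrom,start,end,klass,beta_true
    state_paths: dict[str, np.ndarray] | None = None  # chrom -> per-bin state index
    causal_snp_per_region: pd.DataFrame | None = None  # region_id, snp_id (or NA)
    ai_variants: pd.DataFrame | None = None          # snp_id, ratio_true, imbalanced


def default_state_plan(n_states: int, n_marks: int) -> dict[str, np.ndarray]:
    """Signature matrices for the planted chromatin states.

    State 0 is quiescent. The default 6-state plan over (H3K4me1, H3K27ac,
    H3K4me3) mirrors the enhancer/promoter dichotomy the augmented maps
    resolve: closed/open weak enhancers, closed/open strong enhancers and
    an active promoter; `atac` and `hypometh` flag states with open
    chromatin / hypomethylation.
    """
    if n_states == 6 and n_marks >= 3:
        chip = np.zeros((6, n_marks))
        chip[1, 0] = 1            # closed weak enhancer: H3K4me1
        chip[2, 0] = 1            # open weak enhancer: H3K4me1 + ATAC + hypometh
        chip[3, :2] = 1           # closed strong enhancer: H3K4me1 + H3K27ac
        chip[4, :2] = 1           # open strong enhancer
        chip[5, 2] = 1            # active promoter: H3K4me3
        atac = np.array([0, 0, 1, 0, 1, 1], dtype=bool)
        hypometh = np.array([0, 0, 1, 0, 1, 1], dtype=bool)
    else:
        # generic plan: state s>=1 turns on marks by binary pattern of s
        chip = ((np.arange(n_states)[:, None] >> np.arange(n_marks)[None, :]) & 1).astype(float)
        chip[0] = 0.0
        atac = chip.sum(axis=1) >= max(1, n_marks - 1)
        hypometh = atac.copy()
    return {"chip": chip, "atac": atac, "hypometh": hypometh}


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _cpg_positions(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n_per_chrom = int(config.cpg_density * config.chrom_length / 1000)
    out = {}
    for chrom in config.chrom_names:
        pos = np.unique(rng.integers(0, config.chrom_length - 1, size=n_per_chrom))
        out[chrom] = pos
    return out


def generate_methylome(config: SimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate per-sample WGBS CpG count tables with planted UMRs/LMRs.

    CpG positions are uniform draws at the configured density. A
    hypermethylated background (beta ~ U(0.80, 0.95)) carries planted
    unmethylated regions (UMRs, >30 CpGs, beta ~ U(0.05, 0.20)) and
    low-methylated regions (LMRs, <30 CpGs, beta ~ U(0.10, 0.40)).
    Per sample and CpG: total reads ~ Poisson(coverage), methylated
    reads ~ Binomial(total, beta_true).

    Returns (long-format count table, TruthSet with planted intervals).
    """
    rng = config.rng(_OFF_METHYLOME)
    positions = _cpg_positions(config, rng)

    frames = []
    truth_rows = []
    for chrom in config.chrom_names:
        pos = positions[chrom]
        n = len(pos)
        beta_true = rng.uniform(0.80, 0.95, size=n)

        # plant non-overlapping regions as index ranges with a gap between them
        n_regions = config.n_umr + config.n_lmr
        spans = []
        kinds = []
        for _ in range(config.n_umr):
            spans.append(int(rng.integers(35, 80)))
            kinds.append("UMR")
        for _ in range(config.n_lmr):
            spans.append(int(rng.integers(8, 26)))
            kinds.append("LMR")
        order = rng.permutation(n_regions)
        spans = [spans[i] for i in order]
        kinds = [kinds[i] for i in order]
        total_span = sum(spans)
        gap_budget = n - total_span - 10
        if gap_budget <= n_regions:
            raise InvalidConfigError("genome too small for the planted region count")
        gaps = rng.multinomial(gap_budget - 5 * n_regions, np.ones(n_regions + 1) / (n_regions + 1))
        gaps = gaps + 5  # enforce >=5 background CpGs between regions
        idx = gaps[0]
        for span, kind, gap in zip(spans, kinds, gaps[1:]):
            lo, hi = idx, idx + span
            level = (rng.uniform(0.05, 0.20) if kind == "UMR"
                     else rng.uniform(0.10, 0.40))
            beta_true[lo:hi] = np.clip(level + rng.normal(0, 0.02, size=span), 0.01, 0.49)
            truth_rows.append((chrom, int(pos[lo]), int(pos[hi - 1]) + 2, kind, level, span))
            idx = hi + gap

        totals = rng.poisson(config.per_sample_coverage,
                             size=(config.n_wgbs_samples, n))
        meth = rng.binomial(totals, beta_true[None, :])
        for s in range(config.n_wgbs_samples):
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos,
                "meth_count": meth[s],
                "unmeth_count": totals[s] - meth[s],
                "sample_id": f"islet{s + 1:02d}",
            }))

    table = pd.concat(frames, ignore_index=True)
    truth = TruthSet(umr_lmr_intervals=pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "klass", "beta_true", "n_cpg"]))
    return table, truth


# ---------------------------------------------------------------------------
# Chromatin tracks
# ---------------------------------------------------------------------------

def generate_state_path(config: SimConfig, stay_prob: float = 0.95,
                        quiescent_weight: float = 0.9,
                        truth: TruthSet | None = None) -> TruthSet:
    """Sample a per-bin hidden chromatin-state path for each chromosome.

    A sticky Markov chain (diagonal ``stay_prob``) gives realistic run
    lengths (~4 kb at the default); jump targets are drawn with the
    quiescent state 0 carrying ``quiescent_weight`` of the stationary
    mass, so regulatory marks cover a minority of the genome as in real
    chromatin.
    """
    rng = config.rng(_OFF_STATEPATH)
    K = config.n_states_true
    n_bins = config.chrom_length // config.bin_size
    w = np.full(K, (1.0 - quiescent_weight) / max(K - 1, 1))
    w[0] = quiescent_weight if K > 1 else 1.0
    paths = {}
    for chrom in config.chrom_names:
        path = np.empty(n_bins, dtype=np.int64)
        path[0] = rng.choice(K, p=w)
        stay = rng.random(n_bins) < stay_prob
        # jump targets drawn from w including self: transition matrix
        # stay*I + (1-stay)*1w' whose stationary distribution is exactly w
        jumps = rng.choice(K, size=n_bins, p=w)
        for t in range(1, n_bins):
            path[t] = path[t - 1] if stay[t] else jumps[t]
        paths[chrom] = path
    if truth is None:
        truth = TruthSet()
    truth.state_paths = paths
    return truth


def generate_tracks(config: SimConfig, truth: TruthSet,
                    lam_signal: float = 30.0, lam_bg: float = 5.0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit per-bin ChIP read counts and ATAC peak intervals from the truth path.

    Counts for mark m in a bin with state s are Poisson with rate
    ``lam_signal`` when the planted signature has the mark on, else
    ``lam_bg``. ATAC peaks are the merged runs of bins whose state carries
    the open-chromatin flag.

    Returns (counts table: chrom, bin_index, one column per mark; peaks BED).
    """
    if truth.state_paths is None:
        raise ValueError("truth has no state path; call generate_state_path first")
    rng = config.rng(_OFF_TRACKS)
    plan = default_state_plan(config.n_states_true, config.n_marks)
    lam = np.where(plan["chip"] > 0, lam_signal, lam_bg)  # states x marks

    frames = []
    peak_rows = []
    for chrom in config.chrom_names:
        path = truth.state_paths[chrom]
        n_bins = config.chrom_length // config.bin_size
        if len(path) != n_bins:
            raise ValueError(
                f"state path length {len(path)} does not match {n_bins} bins on {chrom}")
        counts = rng.poisson(lam[path])  # n_bins x n_marks
        df = pd.DataFrame(counts, columns=config.mark_names)
        df.insert(0, "bin_index", np.arange(n_bins))
        df.insert(0, "chrom", chrom)
        frames.append(df)

        open_bins = plan["atac"][path]
        # merged runs of open bins -> peak intervals
        edges = np.flatnonzero(np.diff(np.concatenate([[0], open_bins.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            peak_rows.append((chrom, int(lo) * config.bin_size, int(hi) * config.bin_size))

    counts_df = pd.concat(frames, ignore_index=True)
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    return counts_df, peaks


def sample_binary_tracks(emissions: np.ndarray, transitions: np.ndarray,
                         initial: np.ndarray, length: int, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path and binary observations from a Bernoulli HMM.

    Used for parameter-recovery experiments. Returns (path, X) with X of
    shape (length, n_marks).
    """
    rng = np.random.default_rng(seed)
    K, M = emissions.shape
    path = np.empty(length, dtype=np.int64)
    path[0] = rng.choice(K, p=initial)
    for t in range(1, length):
        path[t] = rng.choice(K, p=transitions[path[t - 1]])
    X = (rng.random((length, M)) < emissions[path]).astype(np.int8)
    return path, X


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def annotation_intervals(config: SimConfig, fraction: float, offset: int = 0
                         ) -> pd.DataFrame:
    """One sub-interval per GWAS region covering ``fraction`` of its span.

    Placement is deterministic given the config seed; ``offset`` decorrelates
    multiple annotations drawn for the same config.
    """
    rng = config.rng(_OFF_ANNOT + 100 * offset)
    span = config.chrom_length // ((config.n_regions // config.n_chroms) + 1)
    rows = []
    for r in range(config.n_regions):
        chrom = config.chrom_names[r % config.n_chroms]
        base = (r // config.n_chroms) * span
        width = max(1, int(fraction * span))
        start = base + int(rng.integers(0, span - width))
        rows.append((chrom, start, start + width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_gwas(config: SimConfig, annotations: dict[str, pd.DataFrame]
                  ) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate GWAS summary statistics under the single-causal-variant model.

    Each region independently harbours a causal SNP with probability Pi
    (``region_prior_true``). The causal SNP is chosen with probability
    proportional to exp(sum_k gamma_k x_ik) over the region's SNPs; its
    true effect is Normal(0, W). Observed effects add Normal(0, SE^2)
    noise; non-causal SNPs are pure noise. z and two-sided p are emitted.
    """
    rng = config.rng(_OFF_GWAS)
    from scipy.stats import norm

    span = config.chrom_length // ((config.n_regions // config.n_chroms) + 1)
    gamma = config.gamma_true
    se = config.gwas_se
    W = config.abf_prior_variance

    rows = []
    causal_rows = []
    snp_counter = 0
    for r in range(config.n_regions):
        chrom = config.chrom_names[r % config.n_chroms]
        base = (r // config.n_chroms) * span
        pos = np.sort(rng.choice(span - 1, size=config.snps_per_region, replace=False)) + base
        ids = [f"rs{snp_counter + i}" for i in range(config.snps_per_region)]
        snp_counter += config.snps_per_region

        x = {}
        score = np.zeros(config.snps_per_region)
        for name, intervals in annotations.items():
            member = points_in_intervals([chrom] * len(pos), pos, intervals).astype(int)
            x[name] = member
            score = score + gamma.get(name, 0.0) * member

        causal_idx = -1
        effect = np.zeros(config.snps_per_region)
        if rng.random() < config.region_prior_true:
            w = np.exp(score - score.max())
            causal_idx = rng.choice(config.snps_per_region, p=w / w.sum())
            effect[causal_idx] = rng.normal(0.0, np.sqrt(W))
        beta_hat = effect + rng.normal(0.0, se, size=config.snps_per_region)
        z = beta_hat / se
        p = 2.0 * norm.sf(np.abs(z))

        df = pd.DataFrame({
            "snp_id": ids, "chrom": chrom, "pos": pos,
            "beta_hat": beta_hat, "se": se, "z": z, "p": p,
        })
        for name in annotations:
            df[f"annot_{name}"] = x[name]
        rows.append(df)
        causal_rows.append((r, ids[causal_idx] if causal_idx >= 0 else pd.NA))

    snps = pd.concat(rows, ignore_index=True)
    truth = TruthSet(causal_snp_per_region=pd.DataFrame(
        causal_rows, columns=["region_id", "causal_snp"]))
    return snps, truth


# ---------------------------------------------------------------------------
# Allele-specific ATAC counts
# ---------------------------------------------------------------------------

def generate_allelic_counts(config: SimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate per-sample ref/alt ATAC read counts at candidate variants.

    Each sample is heterozygous with probability 2f(1-f) (f =
    ``ai_allele_freq``); het samples contribute depth ~
    Poisson(``ai_depth_per_sample``) reads, ref reads ~ Binomial(depth,
    ratio). A planted fraction of variants carries ratio
    ``ai_ratio_true``; the rest are balanced (0.5).
    """
    rng = config.rng(_OFF_ALLELIC)
    f = config.ai_allele_freq
    het_p = 2 * f * (1 - f)
    n_imbalanced = int(round(config.ai_imbalanced_fraction * config.n_ai_variants))
    rows = []
    truth_rows = []
    for v in range(config.n_ai_variants):
        snp_id = f"ai_rs{v}"
        imbalanced = v < n_imbalanced
        ratio = config.ai_ratio_true if imbalanced else 0.5
        truth_rows.append((snp_id, ratio, imbalanced))
        for s in range(config.n_atac_samples):
            het = rng.random() < het_p
            if not het:
                rows.append((snp_id, f"atac{s + 1:02d}", 0, 0, False))
                continue
            depth = rng.poisson(config.ai_depth_per_sample)
            ref = rng.binomial(depth, ratio) if depth > 0 else 0
            rows.append((snp_id, f"atac{s + 1:02d}", ref, depth - ref, True))
    counts = pd.DataFrame(
        rows, columns=["snp_id", "sample_id", "ref_count", "alt_count", "het_flag"])
    truth = TruthSet(ai_variants=pd.DataFrame(
        truth_rows, columns=["snp_id", "ratio_true", "imbalanced"]))
    return counts, truth
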