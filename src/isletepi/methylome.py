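"""WGBS methylome pooling and hypomethylated-region segmentation.

The methylation level (beta) at a CpG is the fraction of methylated read
support, M/(M+U) from sequencing counts and M/(M+U+100) from array signal
intensities. Low-pass per-sample WGBS tables are pooled into a single
high-pass dataset by summing counts; CpGs below a minimum pooled coverage
(default 10X) are dropped.

Hypomethylated regulatory regions are segmented from the pooled betas and
split by CpG content: low-methylated regions (LMRs, fewer than 30 CpGs,
enhancer-like) and unmethylated regions (UMRs, more than 30 CpGs,
promoter-like). Significance is assessed against a permutation null of
the segmentation score with BH-FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests


@dataclass
class HypoMethRegion:
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_beta: float
    klass: str   # "LMR" (<30 CpGs) or "UMR" (>=30 CpGs; boundary 30 -> UMR)
    fdr: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must be < end")
        expected = "LMR" if self.n_cpg < 30 else "UMR"
        if self.klass != expected:
            raise ValueError(f"klass {self.klass} inconsistent with n_cpg={self.n_cpg}")


def array_beta(meth_intensity, unmeth_intensity):
    """Array-convention methylation level: beta = M / (M + U + 100)."""
    m = np.asarray(meth_intensity, dtype=float)
    u = np.asarray(unmeth_intensity, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    return m / (m + u + 100.0)


def pool_samples(table: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Pool per-sample CpG counts into a single high-pass methylome.

    ``table`` is long format with columns chrom, pos, meth_count,
    unmeth_count, sample_id. Counts are summed per CpG across samples;
    CpGs with pooled coverage below ``min_coverage`` are dropped and beta
    is recomputed from the pooled counts.
    """
    if table.duplicated(subset=["chrom", "pos", "sample_id"]).any():
        raise ValueError("duplicate (chrom, pos, sample_id) rows in input")
    pooled = (table.groupby(["chrom", "pos"], sort=True, as_index=False)
              [["meth_count", "unmeth_count"]].sum())
    pooled["coverage"] = pooled["meth_count"] + pooled["unmeth_count"]
    pooled = pooled[pooled["coverage"] >= min_coverage].reset_index(drop=True)
    pooled["beta"] = pooled["meth_count"] / pooled["coverage"]
    return pooled


def _candidate_runs(beta: np.ndarray, cutoff: float, min_cpg: int,
                    smooth_window: int = 3):
    """Maximal runs of >= min_cpg consecutive CpGs with smoothed beta < cutoff.

    Yields (lo, hi) index pairs (half-open). Smoothing is a centred
    running mean over ``smooth_window`` CpGs (edges use the available
    neighbours).
    """
    if len(beta) == 0:
        return
    smoothed = (pd.Series(beta)
                .rolling(smooth_window, center=True, min_periods=1)
                .mean().to_numpy())
    below = smoothed < cutoff
    edges = np.flatnonzero(np.diff(np.concatenate([[0], below.view(np.int8), [0]])))
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= min_cpg:
            yield int(lo), int(hi)


def segment_hypomethylated(pooled: pd.DataFrame, meth_cutoff: float = 0.5,
                           fdr: float = 0.05, n_shuffles: int = 100,
                           min_cpg: int = 4, seed: int = 0,
                           pmd_mask: pd.DataFrame | None = None
                           ) -> pd.DataFrame:
    """Segment pooled betas into FDR-controlled hypomethylated regions.

    Candidates are maximal runs of at least ``min_cpg`` consecutive CpGs
    whose smoothed beta falls below ``meth_cutoff``; each is scored as
    sum(cutoff - beta) over its CpGs. The null is the per-shuffle maximum
    candidate score over ``n_shuffles`` within-chromosome permutations of
    the beta values (a max-statistic permutation null; shuffles with no
    candidate run contribute zero), and candidates are accepted at BH-FDR
    ``fdr`` on the add-one empirical p-values. Accepted regions are
    classed LMR (<30 CpGs) or UMR (otherwise) and returned as a BED-like
    frame (chrom, start, end, n_cpg, mean_beta, klass, q).

    ``pooled`` must be sorted by (chrom, pos). PMDs, if any, must be
    excluded by the caller via ``pmd_mask`` (regions overlapping the mask
    are dropped before scoring).
    """
    for _, grp in pooled.groupby("chrom"):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("pooled input must be sorted by (chrom, pos)")

    rng = np.random.default_rng(seed)
    per_chrom = [(chrom, grp["beta"].to_numpy(), grp["pos"].to_numpy())
                 for chrom, grp in pooled.groupby("chrom", sort=True)]

    candidates = []  # (chrom, pos, beta, lo, hi, score)
    for chrom, beta, pos in per_chrom:
        for lo, hi in _candidate_runs(beta, meth_cutoff, min_cpg):
            score = float(np.sum(meth_cutoff - beta[lo:hi]))
            candidates.append((chrom, pos, beta, lo, hi, score))

    if not candidates:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpg", "mean_beta", "klass", "q"])

    # null: per-shuffle maximum candidate score over within-chromosome
    # beta permutations (0 when a shuffle produces no candidate run)
    null_max = np.zeros(n_shuffles)
    for i in range(n_shuffles):
        best = 0.0
        for _, beta, _ in per_chrom:
            shuffled = rng.permutation(beta)
            for lo, hi in _candidate_runs(shuffled, meth_cutoff, min_cpg):
                best = max(best, float(np.sum(meth_cutoff - shuffled[lo:hi])))
        null_max[i] = best
    null_max = np.sort(null_max)

    obs = np.array([c[5] for c in candidates])
    exceed = n_shuffles - np.searchsorted(null_max, obs, side="left")
    p_emp = (1.0 + exceed) / (n_shuffles + 1.0)
    q = multipletests(p_emp, method="fdr_bh")[1]

    rows = []
    for (chrom, pos, beta, lo, hi, score), qv in zip(candidates, q):
        if qv > fdr:
            continue
        n_cpg = hi - lo
        mean_beta = float(np.mean(beta[lo:hi]))
        region = HypoMethRegion(
            chrom=chrom, start=int(pos[lo]), end=int(pos[hi - 1]) + 2,
            n_cpg=n_cpg, mean_beta=mean_beta,
            klass="LMR" if n_cpg < 30 else "UMR", fdr=float(qv))
        if pmd_mask is not None and len(pmd_mask):
            from .io import intervals_overlap_mask
            hit = intervals_overlap_mask(
                pd.DataFrame([{"chrom": region.chrom, "start": region.start,
                               "end": region.end}]), pmd_mask)
            if hit[0]:
                continue
        rows.append((region.chrom, region.start, region.end, region.n_cpg,
                     region.mean_beta, region.klass, region.fdr))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpg", "mean_beta", "klass", "q"])


def ppa_capture(credible_sets: dict, assayed_cpgs: dict, window: int = 1000):
    """Per-locus PPA captured by an assay's CpG sites, and the median.

    ``credible_sets`` maps locus -> DataFrame with columns chrom, pos,
    ppa (the 99% credible variants). ``assayed_cpgs`` maps chrom -> sorted
    array of assayed CpG positions. A variant is captured when at least
    one assayed CpG lies within +/- ``window`` bp; the locus value is the
    sum of PPA over captured variants. Loci with empty credible sets are
    skipped with a warning.

    Returns (per-locus dict, median captured PPA).
    """
    import warnings

    captured = {}
    for locus, df in credible_sets.items():
        if df is None or len(df) == 0:
            warnings.warn(f"locus {locus}: empty credible set, skipped")
            continue
        total = 0.0
        for chrom, grp in df.groupby("chrom"):
            cpgs = np.asarray(assayed_cpgs.get(chrom, []))
            if len(cpgs) == 0:
                continue
            pos = grp["pos"].to_numpy()
            j = np.searchsorted(cpgs, pos)
            left = np.abs(cpgs[np.clip(j - 1, 0, len(cpgs) - 1)] - pos)
            right = np.abs(cpgs[np.clip(j, 0, len(cpgs) - 1)] - pos)
            near = np.minimum(left, right) <= window
            total += float(grp["ppa"].to_numpy()[near].sum())
        captured[locus] = total
    median = float(np.median(list(captured.values()))) if captured else float("nan")
    return captured, median


def compare_beta_distributions(betas_a, betas_b):
    """Two-sample Kolmogorov-Smirnov comparison of two beta distributions."""
    res = ks_2samp(np.asarray(betas_a), np.asarray(betas_b))
    return float(res.statistic), float(res.pvalue)
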