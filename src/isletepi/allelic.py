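"""Allele-specific chromatin accessibility testing.

Candidate variants (high reweighted PPA, overlapping an enriched
regulatory state) are tested for allelic imbalance by aggregating ATAC
reads across heterozygous samples and applying an exact two-sided
binomial test of the reference-allele fraction against a null ratio
(0.5, or a reference-bias-corrected value); discoveries are controlled
at FDR 0.05 by Benjamini-Hochberg. Mapping-bias removal (read
remapping) is outside this module's contract: counts are assumed
pre-filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests


@dataclass
class AiTestResult:
    snp_id: str
    ref_count: int
    alt_count: int
    n_het_samples: int
    ratio: float
    p: float
    q: float = float("nan")
    significant: bool = False
    direction: str = ""


def aggregate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum per-sample ref/alt counts over heterozygous samples per variant.

    ``counts`` columns: snp_id, sample_id, ref_count, alt_count, het_flag.
    Only het samples with nonzero depth contribute to the het-sample count.
    """
    het = counts[counts["het_flag"].astype(bool)].copy()
    het["depth"] = het["ref_count"] + het["alt_count"]
    agg = (het.groupby("snp_id", as_index=False)
           .agg(ref_count=("ref_count", "sum"),
                alt_count=("alt_count", "sum"),
                n_het_samples=("depth", lambda d: int((d > 0).sum()))))
    return agg


def binomial_ai_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for k reference reads out of n.

    Matches R's ``binom.test``: the two-sided p sums the probabilities of
    all outcomes no more likely than the observed one; for p0 = 0.5 this
    equals doubling the smaller tail (capped at 1).
    """
    if n <= 0:
        raise ValueError("total read count must be positive")
    if not 0 <= k <= n:
        raise ValueError("ref count must lie in [0, n]")
    return float(binomtest(int(k), int(n), p0).pvalue)


def allele_ratio(ref_count: int, alt_count: int) -> float:
    """Reference-allele read fraction, full precision (round for reporting)."""
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("no reads")
    return ref_count / total


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_test_variants(variants: pd.DataFrame, counts: pd.DataFrame,
                         enriched_annotations: list[str],
                         min_ppa: float = 0.10, min_het: int = 2,
                         min_depth: int = 10, min_per_allele: int = 5
                         ) -> pd.DataFrame:
    """Apply the eligibility filters for allelic-imbalance testing.

    A variant is eligible when: reweighted PPA >= ``min_ppa``; it overlaps
    at least one annotation retained in the joint enrichment model
    (columns ``annot_<name>``); it has >= ``min_het`` heterozygous
    samples; aggregate depth >= ``min_depth``; and each allele has
    >= ``min_per_allele`` reads. PPA-eligible variants without count data
    are returned with status "untested" rather than dropped.

    Returns the variant table with aggregated counts and a ``status``
    column ("eligible", "untested", or "filtered").
    """
    agg = aggregate_counts(counts)
    df = variants.merge(agg, on="snp_id", how="left")

    in_enriched = np.zeros(len(df), dtype=bool)
    for a in enriched_annotations:
        col = f"annot_{a}"
        if col in df.columns:
            in_enriched |= df[col].to_numpy(dtype=bool)
    ppa_ok = (df["ppa"] >= min_ppa) & in_enriched

    has_counts = df["ref_count"].notna()
    depth = df["ref_count"].fillna(0) + df["alt_count"].fillna(0)
    counts_ok = (has_counts
                 & (df["n_het_samples"].fillna(0) >= min_het)
                 & (depth >= min_depth)
                 & (df["ref_count"].fillna(0) >= min_per_allele)
                 & (df["alt_count"].fillna(0) >= min_per_allele))

    status = np.where(~ppa_ok, "filtered",
                      np.where(~has_counts, "untested",
                               np.where(counts_ok, "eligible", "filtered")))
    df["status"] = status
    return df


def test_allelic_imbalance(selected: pd.DataFrame, p0: float = 0.5,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Binomial imbalance test + BH FDR over the eligible variants.

    Returns one row per eligible variant with ratio, exact p, q, a
    significance call (q < ``alpha``) and the direction of the more
    accessible allele.
    """
    elig = selected[selected["status"] == "eligible"].copy()
    if elig.empty:
        return pd.DataFrame(columns=[
            "snp_id", "ref_count", "alt_count", "n_het_samples", "ratio",
            "p", "q", "significant", "direction"])
    ref = elig["ref_count"].astype(int).to_numpy()
    alt = elig["alt_count"].astype(int).to_numpy()
    p = np.array([binomial_ai_test(r, r + a, p0) for r, a in zip(ref, alt)])
    q = fdr_adjust(p)
    out = pd.DataFrame({
        "snp_id": elig["snp_id"].to_numpy(),
        "ref_count": ref, "alt_count": alt,
        "n_het_samples": elig["n_het_samples"].astype(int).to_numpy(),
        "ratio": ref / (ref + alt),
        "p": p, "q": q,
        "significant": q < alpha,
        "direction": np.where(ref / (ref + alt) > p0, "ref more open",
                              np.where(ref / (ref + alt) < p0,
                                       "alt more open", "balanced")),
    })
    return out
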