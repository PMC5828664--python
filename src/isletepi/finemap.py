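"""Reweighted posterior probabilities of association and credible sets.

Given a fitted enrichment model, each SNP's posterior probability of
being the causal variant in its window is

    PPA_i = Pi * pi_i * ABF_i / L_r,

so SNPs in globally enriched annotations are afforded extra weight. The
regional PPA (sum over the window) flags significant segments, and 99%
credible sets are the smallest variant sets accounting for 99% of the
(region-normalised) posterior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import EnrichmentFit, RegionSet
from .io import assign_interval_labels


def snp_ppa(regions: RegionSet, fit: EnrichmentFit) -> pd.DataFrame:
    """Per-SNP and regional PPA under the fitted enrichment model.

    Returns the SNP table with added columns ``ppa`` (per-SNP posterior)
    and ``regional_ppa`` (sum over the window, broadcast to its SNPs).
    """
    gamma = np.zeros(len(regions.annotation_names))
    for a, g in fit.gamma.items():
        gamma[regions.annotation_names.index(a)] = g
    score = regions.X @ gamma if gamma.size else np.zeros(len(regions.ln_abf))

    lse_den = regions._grouped_logsumexp(score)
    ln_lr = regions.region_ln_likelihoods(fit.kappa, gamma)
    rep = np.diff(np.concatenate([regions.offsets, [len(score)]]))
    ln_pi_region = -np.log1p(np.exp(-fit.kappa))
    # ln PPA_i = ln Pi + ln pi_i + ln ABF_i - ln L_r
    ln_ppa = (ln_pi_region + (score - np.repeat(lse_den, rep))
              + regions.ln_abf - np.repeat(ln_lr, rep))
    out = regions.snps.copy()
    out["ppa"] = np.exp(ln_ppa)
    regional = np.add.reduceat(out["ppa"].to_numpy(), regions.offsets)
    out["regional_ppa"] = np.repeat(regional, rep)
    return out


def significant_segments(ppa_table: pd.DataFrame, ppa_threshold: float = 0.9,
                         p_threshold: float = 5e-8) -> pd.DataFrame:
    """Regions with regional PPA >= threshold OR a genome-wide significant SNP.

    Returns one row per region: region_id, regional_ppa, min_p, flagged.
    """
    grp = ppa_table.groupby("region_id")
    out = pd.DataFrame({
        "regional_ppa": grp["regional_ppa"].first(),
        "min_p": grp["p"].min() if "p" in ppa_table.columns else np.nan,
    }).reset_index()
    out["flagged"] = (out["regional_ppa"] >= ppa_threshold) | \
                     (out["min_p"] < p_threshold)
    return out


def credible_set(region_table: pd.DataFrame, level: float = 0.99,
                 normalize: bool = True) -> pd.DataFrame:
    """Smallest set of variants whose PPAs sum to >= ``level``.

    ``region_table`` holds one region's SNPs with a ``ppa`` column. PPAs
    are first normalised by the regional total (sets are conditional on
    the region containing a signal) unless ``normalize=False``. Variants
    are sorted by descending PPA with genomic-position tie-break
    (leftmost first); the minimal prefix reaching ``level`` is returned
    with a ``cumulative_ppa`` column.
    """
    total = float(region_table["ppa"].sum())
    if total <= 0:
        raise ValueError("all-zero PPAs: cannot form a credible set")
    df = region_table.copy()
    df["ppa_norm"] = df["ppa"] / total if normalize else df["ppa"]
    df = df.sort_values(["ppa_norm", "pos"], ascending=[False, True],
                        kind="mergesort")
    cum = df["ppa_norm"].cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), level - 1e-12) + 1)
    n_keep = min(n_keep, len(df))
    out = df.iloc[:n_keep].copy()
    out["cumulative_ppa"] = cum.iloc[:n_keep].to_numpy()
    return out


def credible_sets_per_region(ppa_table: pd.DataFrame, level: float = 0.99,
                             region_ids=None) -> dict:
    """99% credible set for each (optionally selected) region."""
    sets = {}
    for rid, grp in ppa_table.groupby("region_id"):
        if region_ids is not None and rid not in set(region_ids):
            continue
        if grp["ppa"].sum() <= 0:
            continue
        sets[rid] = credible_set(grp, level=level)
    return sets


def compare_models(ppa_a: pd.DataFrame, ppa_b: pd.DataFrame,
                   level: float = 0.99, region_ids=None) -> pd.DataFrame:
    """Per-region credible-set size and top-PPA comparison of two models.

    Model ``a`` is the annotation-informed model, ``b`` the baseline.
    ``set_size_reduction`` = size(b) - size(a) (positive = model a gives a
    smaller set); ``top_ppa_increase`` = max PPA(a) - max PPA(b)
    (positive = model a concentrates more posterior on its best variant).
    """
    sets_a = credible_sets_per_region(ppa_a, level, region_ids)
    sets_b = credible_sets_per_region(ppa_b, level, region_ids)
    rows = []
    for rid in sorted(set(sets_a) & set(sets_b)):
        size_a, size_b = len(sets_a[rid]), len(sets_b[rid])
        top_a = float(sets_a[rid]["ppa_norm"].iloc[0])
        top_b = float(sets_b[rid]["ppa_norm"].iloc[0])
        rows.append((rid, size_a, size_b, size_b - size_a, top_a, top_b,
                     top_a - top_b))
    return pd.DataFrame(rows, columns=[
        "region_id", "set_size_a", "set_size_b", "set_size_reduction",
        "top_ppa_a", "top_ppa_b", "top_ppa_increase"])


def partition_ppa_by_state(cred: pd.DataFrame, state_intervals: pd.DataFrame,
                           label_col: str = "name") -> dict:
    """Fraction of a credible set's PPA per chromatin-state label.

    Each variant takes the label of the state interval containing it, or
    "Other" when it falls outside all intervals; the returned fractions
    sum to 1.
    """
    labels = assign_interval_labels(cred["chrom"].to_numpy(),
                                    cred["pos"].to_numpy(),
                                    state_intervals, label_col=label_col)
    w = cred["ppa_norm"] if "ppa_norm" in cred.columns else cred["ppa"]
    w = w.to_numpy()
    total = w.sum()
    out: dict[str, float] = {}
    for lab, weight in zip(labels, w):
        out[lab] = out.get(lab, 0.0) + float(weight) / total
    return out
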