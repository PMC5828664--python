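"""Hierarchical annotation-enrichment model for GWAS summary statistics.

The genome is partitioned into windows of k consecutive SNPs. Each
window either contains exactly one causal SNP (with prior probability
Pi = logistic(kappa)) or none; conditional on the window being causal,
SNP i is the causal one with prior

    pi_i = exp(sum_k gamma_k x_ik) / sum_j exp(sum_k gamma_k x_jk),

where x_ik are binary annotation memberships and gamma_k are
log-enrichment parameters. Per-SNP evidence enters through Wakefield
approximate Bayes factors computed from the effect estimate and its
standard error, averaged over a set of effect-size prior variances W.
The window likelihood is

    L_r = (1 - Pi) + Pi * sum_i pi_i * ABF_i,

maximised over (kappa, gamma) by quasi-Newton optimisation; 95% CIs come
from the profile likelihood (drop of 1.92 = chi2_1(0.95)/2). Enrichments
are estimated on the natural-log scale internally and reported as
log2 fold enrichment (log2FE = gamma / ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2

LN2 = float(np.log(2.0))
#: bound on |log2FE|; hits are flagged rather than treated as estimates
GAMMA_BOUND_LOG2 = 20.0
_CI_DROP = chi2.ppf(0.95, df=1) / 2.0  # 1.9207...

DEFAULT_PRIOR_VARIANCES = (0.01, 0.1, 0.5)


def compute_abf(beta_hat, se, prior_variances=DEFAULT_PRIOR_VARIANCES) -> np.ndarray:
    """Natural-log Wakefield approximate Bayes factor, model-averaged over W.

    ln ABF_W = 0.5*ln(V/(V+W)) + z^2*W / (2*(V+W)) with V = se^2; the
    returned value is ln of the arithmetic mean of ABF_W over
    ``prior_variances``. For case-control data ``beta_hat`` is the log
    odds ratio; the functional form is identical.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(beta_hat)) or np.any(~np.isfinite(se)):
        raise ValueError("non-finite effect estimates or standard errors")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se ** 2
    z2 = (beta_hat / se) ** 2
    lnabf_w = np.stack([
        0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))
        for W in prior_variances
    ])
    return logsumexp(lnabf_w, axis=0) - np.log(len(prior_variances))


class RegionSet:
    """SNPs partitioned into single-causal-variant windows.

    Stores the SNP table plus flat arrays (ln_abf, annotation matrix) and
    region offsets so window-level reductions vectorise with ``reduceat``.
    """

    def __init__(self, snps: pd.DataFrame, annotation_names: list[str]):
        required = {"snp_id", "chrom", "pos", "ln_abf", "region_id"}
        missing = required - set(snps.columns)
        if missing:
            raise ValueError(f"snps table missing columns: {sorted(missing)}")
        self.snps = snps.sort_values(["region_id", "chrom", "pos"],
                                     kind="mergesort").reset_index(drop=True)
        self.annotation_names = list(annotation_names)
        rid = self.snps["region_id"].to_numpy()
        change = np.flatnonzero(np.diff(rid)) + 1
        self.offsets = np.concatenate([[0], change])
        self.region_ids = rid[self.offsets]
        self.ln_abf = self.snps["ln_abf"].to_numpy(dtype=float)
        if annotation_names:
            self.X = self.snps[[f"annot_{a}" for a in annotation_names]] \
                .to_numpy(dtype=float)
        else:
            self.X = np.zeros((len(self.snps), 0))

    @property
    def n_regions(self) -> int:
        return len(self.offsets)

    def subset(self, region_indices) -> "RegionSet":
        keep = set(self.region_ids[list(region_indices)])
        sub = self.snps[self.snps["region_id"].isin(keep)]
        return RegionSet(sub.copy(), self.annotation_names)

    def _grouped_logsumexp(self, values: np.ndarray) -> np.ndarray:
        m = np.maximum.reduceat(values, self.offsets)
        rep = np.diff(np.concatenate([self.offsets, [len(values)]]))
        shifted = np.exp(values - np.repeat(m, rep))
        s = np.add.reduceat(shifted, self.offsets)
        return m + np.log(s)

    def region_ln_likelihoods(self, kappa: float, gamma: np.ndarray) -> np.ndarray:
        """ln L_r for every region; computed in log space without overflow."""
        gamma = np.asarray(gamma, dtype=float)
        score = self.X @ gamma if gamma.size else np.zeros(len(self.ln_abf))
        lse_num = self._grouped_logsumexp(score + self.ln_abf)
        lse_den = self._grouped_logsumexp(score)
        ln_pi = -np.log1p(np.exp(-kappa))          # ln logistic(kappa)
        ln_1mpi = -np.log1p(np.exp(kappa))
        return np.logaddexp(ln_1mpi, ln_pi + lse_num - lse_den)

    def ln_likelihood(self, kappa: float, gamma: np.ndarray) -> float:
        return float(self.region_ln_likelihoods(kappa, gamma).sum())


def segment_genome(snps: pd.DataFrame, k: int = 5000,
                   annotation_names: list[str] | None = None,
                   prior_variances=DEFAULT_PRIOR_VARIANCES) -> RegionSet:
    """Partition SNPs into windows of ``k`` consecutive SNPs per chromosome.

    SNPs are sorted by (chrom, pos); windows never span chromosomes and
    the final partial window on each chromosome is kept. Adds a
    ``region_id`` column. Annotation membership columns are expected as
    ``annot_<name>``; by default every such column is used.
    """
    snps = snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    region_ids = np.empty(len(snps), dtype=np.int64)
    next_id = 0
    for _, grp in snps.groupby("chrom", sort=True):
        n = len(grp)
        local = np.arange(n) // k
        region_ids[grp.index.to_numpy()] = local + next_id
        next_id += local[-1] + 1 if n else 0
    snps = snps.copy()
    snps["region_id"] = region_ids
    if "ln_abf" not in snps.columns:
        snps["ln_abf"] = compute_abf(snps["beta_hat"], snps["se"],
                                     prior_variances=prior_variances)
    if annotation_names is None:
        annotation_names = [c[len("annot_"):] for c in snps.columns
                            if c.startswith("annot_")]
    return RegionSet(snps, annotation_names)


@dataclass
class EnrichmentFit:
    """Maximum-likelihood enrichment estimates for a set of annotations."""

    kappa: float                       # region-prior intercept, Pi = logistic(kappa)
    gamma: dict                        # annotation -> natural-log enrichment
    ci_lo: dict                        # 95% bounds on the log2FE scale
    ci_hi: dict
    ln_likelihood: float               # unpenalised, at the fitted parameters
    included: list[str] = field(default_factory=list)
    penalty: float = 0.0
    at_bound: dict = field(default_factory=dict)

    @property
    def region_prior(self) -> float:
        return float(expit(self.kappa))

    @property
    def log2fe(self) -> dict:
        return {a: g / LN2 for a, g in self.gamma.items()}

    def significant(self, annotation: str) -> bool:
        """Enriched iff the estimate and its 95% CI lie above zero."""
        return self.ci_lo[annotation] > 0.0

    def summary(self) -> pd.DataFrame:
        rows = [(a, self.log2fe[a], self.ci_lo[a], self.ci_hi[a],
                 self.significant(a), self.at_bound.get(a, False))
                for a in self.included]
        return pd.DataFrame(rows, columns=[
            "annotation", "log2fe", "ci_lo", "ci_hi", "significant", "at_bound"])


_GB = GAMMA_BOUND_LOG2 * LN2  # natural-log bound


def _check_identifiable(regions: RegionSet, names: list[str]) -> None:
    for a in names:
        col = regions.X[:, regions.annotation_names.index(a)]
        if col.sum() == 0 or col.sum() == len(col):
            raise ValueError(
                f"annotation '{a}' covers none or all SNPs and is unidentifiable")


def _ml_fit(regions: RegionSet, names: list[str], penalty: float = 0.0,
            x0: np.ndarray | None = None):
    """Maximise the (optionally L1-penalised) log-likelihood over (kappa, gamma)."""
    idx = [regions.annotation_names.index(a) for a in names]

    def neg(theta):
        kappa = theta[0]
        gamma = np.zeros(len(regions.annotation_names))
        gamma[idx] = theta[1:]
        ll = regions.ln_likelihood(kappa, gamma)
        return -(ll - penalty * np.abs(theta[1:]).sum())

    if x0 is None:
        x0 = np.zeros(1 + len(names))
    bounds = [(-15.0, 15.0)] + [(-_GB, _GB)] * len(names)
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                   options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500})
    kappa = float(res.x[0])
    gamma_full = np.zeros(len(regions.annotation_names))
    gamma_full[idx] = res.x[1:]
    ln_l = regions.ln_likelihood(kappa, gamma_full)
    return kappa, dict(zip(names, res.x[1:])), ln_l


def _profile_ci(regions: RegionSet, names: list[str], target: str,
                kappa_hat: float, gamma_hat: dict, ln_l_hat: float):
    """Profile-likelihood 95% CI for one annotation's gamma (log2 scale).

    Other parameters are re-optimised at each profiled value; bounds are
    where the profile drops by chi2_1(0.95)/2 = 1.92. A bound that hits
    the gamma box is reported at the box edge and flagged.
    """
    others = [a for a in names if a != target]
    t_idx = regions.annotation_names.index(target)
    o_idx = [regions.annotation_names.index(a) for a in others]

    def prof(g):
        def neg(theta):
            gamma = np.zeros(len(regions.annotation_names))
            gamma[t_idx] = g
            gamma[o_idx] = theta[1:]
            return -regions.ln_likelihood(theta[0], gamma)
        x0 = np.concatenate([[kappa_hat], [gamma_hat[a] for a in others]])
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-15.0, 15.0)] + [(-_GB, _GB)] * len(others),
                       options={"ftol": 1e-12, "maxiter": 300})
        return -res.fun

    g_hat = gamma_hat[target]
    crit = ln_l_hat - _CI_DROP

    def f(g):
        return prof(g) - crit

    at_bound = False

    def search(direction):
        nonlocal at_bound
        step = 0.25
        g = g_hat
        val = f(g)
        for _ in range(200):
            g_next = g + direction * step
            if abs(g_next) >= _GB:
                at_bound = True
                return direction * _GB
            v_next = f(g_next)
            if v_next < 0:
                return brentq(f, min(g, g_next), max(g, g_next), xtol=1e-4)
            g, val = g_next, v_next
            step *= 1.6
        at_bound = True
        return direction * _GB

    lo = search(-1.0)
    hi = search(+1.0)
    return lo / LN2, hi / LN2, at_bound


def fit_single(regions: RegionSet, annotation: str,
               compute_ci: bool = True) -> EnrichmentFit:
    """Fit the enrichment model with a single annotation.

    Returns the ML (kappa, gamma) with a profile-likelihood 95% CI; the
    annotation is significantly enriched when the lower CI bound is
    above zero.
    """
    _check_identifiable(regions, [annotation])
    kappa, gamma, ln_l = _ml_fit(regions, [annotation])
    if compute_ci:
        lo, hi, at_bound = _profile_ci(regions, [annotation], annotation,
                                       kappa, gamma, ln_l)
    else:
        lo, hi, at_bound = float("nan"), float("nan"), False
    return EnrichmentFit(
        kappa=kappa, gamma=gamma,
        ci_lo={annotation: lo}, ci_hi={annotation: hi},
        ln_likelihood=ln_l, included=[annotation],
        at_bound={annotation: at_bound})


def fit_null(regions: RegionSet) -> EnrichmentFit:
    """Annotation-free fit (kappa only)."""
    kappa, _, ln_l = _ml_fit(regions, [])
    return EnrichmentFit(kappa=kappa, gamma={}, ci_lo={}, ci_hi={},
                         ln_likelihood=ln_l, included=[])


def _cv_ln_likelihood(regions: RegionSet, names: list[str], penalty: float,
                      folds: list[np.ndarray]) -> float:
    """Sum of held-out unpenalised log-likelihoods over CV folds."""
    total = 0.0
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        train = regions.subset(train_idx)
        test = regions.subset(test_idx)
        kappa, gamma, _ = _ml_fit(train, names, penalty=penalty)
        gvec = np.zeros(len(test.annotation_names))
        for a, g in gamma.items():
            gvec[test.annotation_names.index(a)] = g
        total += test.ln_likelihood(kappa, gvec)
    return total


def fit_joint(regions: RegionSet, candidates: list[str],
              penalty: float | None = None,
              penalty_grid=(0.0, 0.05, 0.1, 0.2, 0.5),
              n_folds: int = 10, seed: int = 0,
              compute_ci: bool = True) -> EnrichmentFit:
    """Forward-selection joint model with cross-validated L1 penalty.

    Candidates (typically the annotations significant in single fits)
    are added greedily by maximum log-likelihood gain. The L1 penalty is
    chosen by ``n_folds``-fold cross-validation over regions (unless
    given), then annotations are dropped while the cross-validation
    likelihood improves. Returns the final model with per-annotation
    estimates and profile CIs; with no candidates an intercept-only fit
    is returned.
    """
    candidates = list(candidates)
    if not candidates:
        return fit_null(regions)
    _check_identifiable(regions, candidates)

    # forward selection by ML gain
    included: list[str] = []
    _, _, current_ll = _ml_fit(regions, included)
    remaining = candidates.copy()
    while remaining:
        gains = []
        for a in remaining:
            _, _, ll = _ml_fit(regions, included + [a])
            gains.append(ll - current_ll)
        best = int(np.argmax(gains))
        if gains[best] <= 1e-9:
            break
        included.append(remaining.pop(best))
        current_ll += gains[best]

    if not included:
        return fit_null(regions)

    rng = np.random.default_rng(seed)
    order = rng.permutation(regions.n_regions)
    folds = np.array_split(order, n_folds)

    if penalty is None:
        cv_scores = [_cv_ln_likelihood(regions, included, p, folds)
                     for p in penalty_grid]
        penalty = float(penalty_grid[int(np.argmax(cv_scores))])

    # backward elimination while CV likelihood improves
    cv_full = _cv_ln_likelihood(regions, included, penalty, folds)
    while len(included) > 1:
        trials = [(a, _cv_ln_likelihood(regions, [b for b in included if b != a],
                                        penalty, folds))
                  for a in included]
        drop, best_cv = max(trials, key=lambda t: t[1])
        if best_cv > cv_full:
            included.remove(drop)
            cv_full = best_cv
        else:
            break

    kappa, gamma, ln_l = _ml_fit(regions, included, penalty=penalty)
    ci_lo, ci_hi, at_bound = {}, {}, {}
    if compute_ci:
        for a in included:
            lo, hi, ab = _profile_ci(regions, included, a, kappa, gamma, ln_l)
            ci_lo[a], ci_hi[a], at_bound[a] = lo, hi, ab
    else:
        for a in included:
            ci_lo[a] = ci_hi[a] = float("nan")
            at_bound[a] = False
    return EnrichmentFit(kappa=kappa, gamma=gamma, ci_lo=ci_lo, ci_hi=ci_hi,
                         ln_likelihood=ln_l, included=included, penalty=penalty,
                         at_bound=at_bound)


def lrt_nested(full: EnrichmentFit, reduced: EnrichmentFit):
    """Likelihood-ratio test of a reduced model against a nesting full model.

    Uses the unpenalised log-likelihoods stored on the fits; the statistic
    2*(lnL_full - lnL_reduced) is referred to chi-square with df equal to
    the difference in annotation count.
    """
    if not set(reduced.included) <= set(full.included):
        raise ValueError("models are not nested")
    df = len(full.included) - len(reduced.included)
    stat = 2.0 * (full.ln_likelihood - reduced.ln_likelihood)
    if df == 0:
        return float(stat), 1.0
    stat = max(stat, 0.0)
    return float(stat), float(chi2.sf(stat, df))
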