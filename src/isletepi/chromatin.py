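"""Chromatin-state segmentation over 200 bp genomic bins.

Epigenomic tracks (ChIP read counts, ATAC peaks, CpG methylation) are
binarised per bin and jointly modelled with a multivariate hidden Markov
model whose emissions are independent Bernoulli probabilities per mark —
the same model family used for reference chromatin-state maps. Learning
is Baum-Welch EM with per-position scaling; decoding is posterior
(forward-backward) with hard assignment by argmax. States are labelled
semantically from their emission vectors, subdividing enhancers by
open-chromatin and methylation status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .io import intervals_overlap_mask

try:  # jitted forward-backward core; numpy fallback below
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


@dataclass
class StateModel:
    """Bernoulli-emission HMM over binary epigenomic marks."""

    emissions: np.ndarray          # (n_states, n_marks) Bernoulli probabilities
    transitions: np.ndarray        # (n_states, n_states), rows sum to 1
    initial: np.ndarray            # (n_states,)
    mark_names: list[str]
    labels: list[str] | None = None
    log_likelihood: float = float("nan")
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.n_states
        if self.transitions.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.emissions < 0) or np.any(self.emissions > 1):
            raise ValueError("emission probabilities must lie in [0, 1]")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    @property
    def n_marks(self) -> int:
        return self.emissions.shape[1]


# ---------------------------------------------------------------------------
# Binarisation
# ---------------------------------------------------------------------------

def binarize_chip(counts, threshold_p: float = 1e-4) -> np.ndarray:
    """Poisson upper-tail binarisation of a per-bin read-count track.

    A bin is called present (1) when P(X >= count) < ``threshold_p``
    under a Poisson with rate equal to the genome-wide mean count per bin.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lam = counts.mean()
    if lam == 0:
        warnings.warn("all-zero track: binarisation returns all zeros")
        return np.zeros(len(counts), dtype=np.int8)
    tail = poisson.sf(counts - 1, lam)  # P(X >= count)
    return (tail < threshold_p).astype(np.int8)


def binarize_methylation(pooled: pd.DataFrame, chrom: str, n_bins: int,
                         bin_size: int = 200, cutoff: float = 0.6) -> np.ndarray:
    """Hypomethylation flag per bin: 1 iff mean bin beta < cutoff.

    Bins containing no CpG are 0 (absence convention); a bin whose mean
    beta equals the cutoff exactly is hypermethylated (flag 0).
    """
    sub = pooled[pooled["chrom"] == chrom]
    flags = np.zeros(n_bins, dtype=np.int8)
    if len(sub) == 0:
        return flags
    bins = (sub["pos"].to_numpy() // bin_size).astype(int)
    ok = bins < n_bins
    bins = bins[ok]
    beta = sub["beta"].to_numpy()[ok]
    sums = np.bincount(bins, weights=beta, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    has = counts > 0
    mean_beta = np.zeros(n_bins)
    mean_beta[has] = sums[has] / counts[has]
    flags[has & (mean_beta < cutoff)] = 1
    return flags


def binarize_atac(peaks: pd.DataFrame, chrom: str, n_bins: int,
                  bin_size: int = 200) -> np.ndarray:
    """Peak presence per bin: 1 iff the bin overlaps any peak by >= 1 bp."""
    bins = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n_bins) * bin_size,
        "end": (np.arange(n_bins) + 1) * bin_size,
    })
    if len(peaks) == 0:
        return np.zeros(n_bins, dtype=np.int8)
    return intervals_overlap_mask(bins, peaks).astype(np.int8)


# ---------------------------------------------------------------------------
# Forward-backward with per-position scaling
# ---------------------------------------------------------------------------

def _emission_probs(X: np.ndarray, emissions: np.ndarray):
    """Row-scaled P(x_t | state); returns (B, shift) with shape (T, K), (T,).

    The per-row shift keeps B away from underflow even with many marks;
    it cancels in the posteriors and is added back to the log-likelihood.
    """
    logp = np.log(np.clip(emissions, 1e-12, 1.0))
    logq = np.log(np.clip(1.0 - emissions, 1e-12, 1.0))
    logB = X @ logp.T + (1 - X) @ logq.T
    shift = logB.max(axis=1)
    return np.exp(logB - shift[:, None]), shift


def _fb_core_numpy(B: np.ndarray, A: np.ndarray, initial: np.ndarray):
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    alpha[0] = initial * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi_sum += (alpha[t][:, None] * A) * \
            (B[t + 1] * beta[t + 1])[None, :] / c[t + 1]
    return gamma, xi_sum, float(np.log(c).sum())


if njit is not None:
    @njit(cache=False)
    def _fb_core_jit(B, A, initial):  # pragma: no cover - exercised via wrapper
        T, K = B.shape
        alpha = np.empty((T, K))
        c = np.empty(T)
        s = 0.0
        for k in range(K):
            alpha[0, k] = initial[k] * B[0, k]
            s += alpha[0, k]
        c[0] = s
        for k in range(K):
            alpha[0, k] /= s
        for t in range(1, T):
            s = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[t, j]
                s += alpha[t, j]
            c[t] = s
            for j in range(K):
                alpha[t, j] /= s

        beta = np.empty((T, K))
        for k in range(K):
            beta[T - 1, k] = 1.0
        for t in range(T - 2, -1, -1):
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]

        gamma = np.empty((T, K))
        for t in range(T):
            s = 0.0
            for k in range(K):
                gamma[t, k] = alpha[t, k] * beta[t, k]
                s += gamma[t, k]
            for k in range(K):
                gamma[t, k] /= s

        xi_sum = np.zeros((K, K))
        for t in range(T - 1):
            for i in range(K):
                for j in range(K):
                    xi_sum[i, j] += alpha[t, i] * A[i, j] * B[t + 1, j] * \
                        beta[t + 1, j] / c[t + 1]
        ln_c = 0.0
        for t in range(T):
            ln_c += np.log(c[t])
        return gamma, xi_sum, ln_c
else:  # pragma: no cover
    _fb_core_jit = None


def _forward_backward(X: np.ndarray, model: StateModel):
    """Scaled forward-backward. Returns (gamma, xi_sum, ln_likelihood).

    gamma[t, k] = P(state_t = k | X); xi_sum[i, j] = sum_t P(s_t=i, s_t+1=j | X).
    The per-position row scaling of the emission matrix cancels in the
    posteriors and is corrected in the returned log-likelihood.
    """
    T = X.shape[0]
    B, shift = _emission_probs(X, model.emissions)
    core = _fb_core_jit if _fb_core_jit is not None else _fb_core_numpy
    gamma, xi_sum, ln_c = core(B, model.transitions, model.initial)
    ln_l = float(ln_c + shift.sum()) if T else 0.0
    return gamma, xi_sum, ln_l


def decode_states(model: StateModel, X: np.ndarray):
    """Posterior state probabilities and argmax assignment per bin."""
    X = np.asarray(X)
    gamma, _, _ = _forward_backward(X, model)
    return gamma.argmax(axis=1), gamma


# ---------------------------------------------------------------------------
# Baum-Welch learning
# ---------------------------------------------------------------------------

def _init_model(X_all: np.ndarray, n_states: int, mark_names, rng,
                diag_boost: float = 0.5) -> StateModel:
    """Random restart initialisation.

    Emissions seed from observed mark vectors (drawn with probability
    proportional to frequency, without replacement where possible) and
    are softened towards 0/1; this separates sparse co-occurrence
    patterns far better than perturbing the global marginals. Remaining
    states fall back to marginal perturbation.
    """
    marginals = X_all.mean(axis=0)
    uniq, counts = np.unique(X_all, axis=0, return_counts=True)
    n_seed = min(n_states, len(uniq))
    picks = rng.choice(len(uniq), size=n_seed, replace=False,
                       p=counts / counts.sum())
    emissions = np.empty((n_states, X_all.shape[1]))
    emissions[:n_seed] = 0.7 * uniq[picks] + 0.15
    if n_seed < n_states:
        emissions[n_seed:] = np.clip(
            marginals[None, :] + rng.uniform(-0.3, 0.3,
                                             size=(n_states - n_seed,
                                                   len(marginals))),
            0.05, 0.95)
    emissions += rng.uniform(-0.05, 0.05, size=emissions.shape)
    emissions = np.clip(emissions, 0.02, 0.98)
    A = np.full((n_states, n_states), (1.0 - diag_boost) / max(n_states - 1, 1))
    np.fill_diagonal(A, diag_boost if n_states > 1 else 1.0)
    A = A * rng.uniform(0.9, 1.1, size=A.shape)
    A /= A.sum(axis=1, keepdims=True)
    initial = np.full(n_states, 1.0 / n_states)
    return StateModel(emissions, A, initial, list(mark_names))


def learn_model(tracks, n_states: int = 15, n_restarts: int = 5, seed: int = 0,
                tol: float = 1e-4, max_iter: int = 200,
                mark_names: list[str] | None = None) -> StateModel:
    """Fit the Bernoulli-emission HMM by Baum-Welch EM.

    ``tracks`` is either a single (T, n_marks) binary matrix or a list of
    such matrices (chromosomes treated as independent sequences sharing
    parameters). The best of ``n_restarts`` random initialisations by
    final log-likelihood is returned; within a run the log-likelihood is
    non-decreasing and iteration stops when the improvement falls below
    ``tol`` or ``max_iter`` is reached.
    """
    if isinstance(tracks, np.ndarray):
        seqs = [np.asarray(tracks, dtype=np.int8)]
    else:
        seqs = [np.asarray(t, dtype=np.int8) for t in tracks]
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    X_all = np.concatenate(seqs, axis=0)
    if mark_names is None:
        mark_names = [f"mark{i}" for i in range(X_all.shape[1])]
    n_distinct = len(np.unique(X_all, axis=0))
    if n_states > n_distinct:
        warnings.warn(
            f"n_states={n_states} exceeds the {n_distinct} distinct mark vectors; "
            "the fit may be degenerate")

    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        model = _init_model(X_all, n_states, mark_names, rng)
        history: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            gammas, xi_total, ll = [], np.zeros((n_states, n_states)), 0.0
            init_acc = np.zeros(n_states)
            for X in seqs:
                g, xi, l = _forward_backward(X, model)
                gammas.append(g)
                xi_total += xi
                init_acc += g[0]
                ll += l
            history.append(ll)
            G = np.concatenate(gammas, axis=0)
            denom = G.sum(axis=0)[:, None]
            emissions = np.clip((G.T @ X_all) / denom, 1e-6, 1 - 1e-6)
            A = xi_total / np.clip(xi_total.sum(axis=1, keepdims=True), 1e-300, None)
            initial = init_acc / init_acc.sum()
            model = StateModel(emissions, A, initial, list(mark_names))
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        model.log_likelihood = history[-1]
        model.ll_history = history
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def match_states(model: StateModel, reference_emissions: np.ndarray) -> np.ndarray:
    """Hungarian matching of model states to reference states.

    Returns perm with perm[reference_state] = model_state, maximising
    emission-vector agreement (minimising L1 distance). Label switching
    is inherent to HMMs; use this before comparing planted and fitted
    parameters.
    """
    from scipy.optimize import linear_sum_assignment

    ref = np.asarray(reference_emissions)
    cost = np.abs(ref[:, None, :] - model.emissions[None, :, :]).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols


# ---------------------------------------------------------------------------
# Semantic state labels
# ---------------------------------------------------------------------------

#: rule table: (label, required marks, forbidden marks), evaluated in order;
#: a mark "counts" when its emission probability exceeds the threshold.
DEFAULT_LABEL_RULES = [
    ("active promoter", ("H3K4me3",), ()),
    ("open strong enhancer", ("H3K4me1", "H3K27ac", "ATAC", "hypometh"), ()),
    ("lowly-methylated strong enhancer", ("H3K4me1", "H3K27ac", "hypometh"), ("ATAC",)),
    ("closed strong enhancer", ("H3K4me1", "H3K27ac"), ()),
    ("open weak enhancer", ("H3K4me1", "ATAC", "hypometh"), ("H3K27ac",)),
    ("lowly-methylated weak enhancer", ("H3K4me1", "hypometh"), ("H3K27ac", "ATAC")),
    ("closed weak enhancer", ("H3K4me1",), ("H3K27ac",)),
    ("transcribed", ("H3K36me3",), ()),
    ("insulator", ("CTCF",), ()),
    ("polycomb repressed", ("H3K27me3",), ()),
    ("accessible chromatin", ("ATAC",), ("H3K4me1", "H3K27ac", "H3K4me3")),
    ("low methylation", ("hypometh",), ("H3K4me1", "H3K27ac", "H3K4me3")),
]


def label_states(model: StateModel, rules=None, threshold: float = 0.5) -> StateModel:
    """Assign a semantic label to each state from its emission vector.

    A state "has" a mark when the emission probability exceeds
    ``threshold``. The first rule whose required marks are all present
    and forbidden marks all absent wins; states matching no rule are
    labelled "quiescent".
    """
    if rules is None:
        rules = DEFAULT_LABEL_RULES
    has = {name: model.emissions[:, i] > threshold
           for i, name in enumerate(model.mark_names)}
    labels = []
    for k in range(model.n_states):
        label = "quiescent"
        for name, req, forb in rules:
            if all(has.get(m, np.zeros(model.n_states, bool))[k] for m in req) and \
               not any(has.get(m, np.zeros(model.n_states, bool))[k] for m in forb):
                label = name
                break
        labels.append(label)
    model.labels = labels
    return model


def states_to_bed(chrom: str, path: np.ndarray, labels: list[str],
                  bin_size: int = 200) -> pd.DataFrame:
    """Collapse a per-bin state path into labelled BED intervals."""
    rows = []
    T = len(path)
    start = 0
    for t in range(1, T + 1):
        if t == T or path[t] != path[t - 1]:
            rows.append((chrom, start * bin_size, t * bin_size,
                         labels[path[t - 1]], int(path[t - 1])))
            start = t
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "state"])
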