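"""Binarisation, Bernoulli-HMM learning/decoding, semantic labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from isletepi import chromatin as ch
from isletepi import synthetic as syn


class TestBinarizeChip:
    def test_extreme_count_called_present(self):
        counts = np.full(1000, 5)
        counts[10] = 30  # P(X>=30 | lam~5) ~ 2e-15
        out = ch.binarize_chip(counts)
        assert out[10] == 1 and out.sum() == 1

    def test_mean_count_not_called(self):
        counts = np.full(1000, 5)
        assert ch.binarize_chip(counts).sum() == 0

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = ch.binarize_chip(np.zeros(10))
        assert out.sum() == 0

    def test_recovers_planted_marks(self, small_config):
        """Poisson separation lam 30 vs 5 recovers planted presence >99%."""
        truth = syn.generate_state_path(small_config)
        counts, _ = syn.generate_tracks(small_config, truth)
        plan = syn.default_state_plan(small_config.n_states_true,
                                      small_config.n_marks)
        acc = []
        for chrom in small_config.chrom_names:
            sub = counts[counts["chrom"] == chrom]
            path = truth.state_paths[chrom]
            for j, mark in enumerate(small_config.mark_names):
                called = ch.binarize_chip(sub[mark].to_numpy())
                planted = plan["chip"][path, j] > 0
                acc.append((called == planted).mean())
        assert np.mean(acc) > 0.99


class TestBinarizeMethylation:
    def test_boundary_at_cutoff(self):
        pooled = pd.DataFrame({"chrom": ["c"] * 2, "pos": [50, 250],
                               "beta": [0.59, 0.60]})
        flags = ch.binarize_methylation(pooled, "c", n_bins=3)
        assert flags.tolist() == [1, 0, 0]  # 0.59 hypo, 0.60 exactly -> hyper

    def test_empty_bin_is_zero(self):
        pooled = pd.DataFrame({"chrom": ["c"], "pos": [450], "beta": [0.1]})
        flags = ch.binarize_methylation(pooled, "c", n_bins=4)
        assert flags.tolist() == [0, 0, 1, 0]

    def test_hypermethylated_genome_all_zero(self):
        pooled = pd.DataFrame({"chrom": "c", "pos": np.arange(0, 2000, 37),
                               "beta": 0.9})
        assert ch.binarize_methylation(pooled, "c", n_bins=10).sum() == 0


class TestBinarizeAtac:
    def test_partial_overlap_sets_spanned_bins(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [1400]})
        flags = ch.binarize_atac(peaks, "c", n_bins=10)
        assert np.flatnonzero(flags).tolist() == [5, 6]

    def test_empty_peaks(self):
        peaks = pd.DataFrame(columns=["chrom", "start", "end"])
        assert ch.binarize_atac(peaks, "c", n_bins=5).sum() == 0

    def test_exact_bin_peak(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [600], "end": [800]})
        flags = ch.binarize_atac(peaks, "c", n_bins=10)
        assert np.flatnonzero(flags).tolist() == [3]


def planted_two_state(length=10_000, seed=3):
    em = np.array([[0.9, 0.1], [0.1, 0.9]])
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    path, X = syn.sample_binary_tracks(em, A, np.array([0.5, 0.5]), length, seed)
    return em, A, path, X


@pytest.fixture(scope="module")
def two_state_fit():
    em, A, path, X = planted_two_state()
    model = ch.learn_model(X, n_states=2, n_restarts=3, seed=0)
    return em, path, X, model


class TestLearnModel:
    def test_two_state_parameter_recovery(self, two_state_fit):
        em, path, X, model = two_state_fit
        perm = ch.match_states(model, em)
        assert np.abs(model.emissions[perm] - em).max() < 0.05
        dec, _ = ch.decode_states(model, X)
        inv = np.empty(2, dtype=int)
        inv[perm] = np.arange(2)
        assert (inv[dec] == path).mean() > 0.95

    def test_decoding_beats_marginal_classifier(self, two_state_fit):
        em, path, X, model = two_state_fit
        perm = ch.match_states(model, em)
        inv = np.empty(2, dtype=int)
        inv[perm] = np.arange(2)
        dec, _ = ch.decode_states(model, X)
        hmm_acc = (inv[dec] == path).mean()
        # marginal classifier: predict the majority planted state always
        marginal_acc = max(np.mean(path == 0), np.mean(path == 1))
        assert hmm_acc > marginal_acc

    def test_single_state_data_collapses_to_marginals(self):
        """Fitting 2 states to i.i.d. data is non-identifiable (any split
        along the likelihood ridge is ML); the identifiable quantity is
        the stationary mixture of emissions, which must reproduce the
        generating per-mark probabilities."""
        rng = np.random.default_rng(4)
        probs = np.array([0.3, 0.7])
        X = (rng.random((4000, 2)) < probs).astype(np.int8)
        model = ch.learn_model(X, n_states=2, n_restarts=1, seed=1)
        evals, evecs = np.linalg.eig(model.transitions.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat = stat / stat.sum()
        mixed = stat @ model.emissions
        assert np.abs(mixed - probs).max() < 0.05

    def test_loglikelihood_monotone(self):
        _, _, _, X = planted_two_state(length=2000)
        model = ch.learn_model(X, n_states=3, n_restarts=1, seed=2)
        diffs = np.diff(model.ll_history)
        assert np.all(diffs >= -1e-8)

    def test_transition_rows_and_initial_normalised(self):
        _, _, _, X = planted_two_state(length=2000)
        model = ch.learn_model(X, n_states=2, n_restarts=1, seed=0)
        assert np.allclose(model.transitions.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(model.initial.sum(), 1.0, atol=1e-9)

    def test_excess_states_warns(self):
        X = np.zeros((100, 2), dtype=np.int8)
        X[::2] = 1
        with pytest.warns(UserWarning, match="distinct mark vectors"):
            ch.learn_model(X, n_states=4, n_restarts=1, seed=0, max_iter=5)


class TestDecodeStates:
    def test_deterministic_emissions_recover_path_exactly(self):
        em = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = ch.StateModel(em, A, np.array([0.5, 0.5]), ["a", "b"])
        path, X = syn.sample_binary_tracks(em, A, np.array([0.5, 0.5]),
                                           500, seed=9)
        dec, post = ch.decode_states(model, X)
        assert np.array_equal(dec, path)
        assert np.allclose(post.max(axis=1), 1.0)

    def test_uninformative_model_gives_uniform_posteriors(self):
        em = np.full((2, 2), 0.5)
        A = np.full((2, 2), 0.5)
        model = ch.StateModel(em, A, np.array([0.5, 0.5]), ["a", "b"])
        X = np.random.default_rng(0).integers(0, 2, (50, 2)).astype(np.int8)
        _, post = ch.decode_states(model, X)
        assert np.allclose(post, 0.5)

    def test_agrees_with_exhaustive_path_enumeration(self):
        """Forward-backward posteriors equal brute-force sums over all
        2^10 state paths on a 10-bin toy."""
        rng = np.random.default_rng(5)
        em = rng.uniform(0.1, 0.9, (2, 3))
        A = rng.dirichlet(np.ones(2), size=2)
        init = rng.dirichlet(np.ones(2))
        model = ch.StateModel(em, A, init, ["a", "b", "c"])
        X = rng.integers(0, 2, (10, 3)).astype(np.int8)

        post_marg = np.zeros((10, 2))
        for states in itertools.product(range(2), repeat=10):
            lp = np.log(init[states[0]])
            for t in range(1, 10):
                lp += np.log(A[states[t - 1], states[t]])
            for t in range(10):
                e = em[states[t]]
                lp += np.sum(X[t] * np.log(e) + (1 - X[t]) * np.log(1 - e))
            for t in range(10):
                post_marg[t, states[t]] += np.exp(lp)
        post_marg /= post_marg.sum(axis=1, keepdims=True)

        _, post = ch.decode_states(model, X)
        assert np.abs(post - post_marg).max() < 1e-10


class TestLabelStates:
    def make_model(self, emission_rows, marks):
        K = len(emission_rows)
        A = np.full((K, K), 1.0 / K)
        return ch.StateModel(np.array(emission_rows), A, np.full(K, 1.0 / K),
                             marks)

    MARKS = ["H3K4me1", "H3K27ac", "H3K4me3", "ATAC", "hypometh"]

    @pytest.mark.parametrize("row,expected", [
        ([0.9, 0.9, 0.1, 0.9, 0.9], "open strong enhancer"),
        ([0.9, 0.1, 0.1, 0.1, 0.1], "closed weak enhancer"),
        ([0.9, 0.1, 0.1, 0.9, 0.9], "open weak enhancer"),
        ([0.9, 0.9, 0.1, 0.1, 0.1], "closed strong enhancer"),
        ([0.9, 0.1, 0.1, 0.1, 0.9], "lowly-methylated weak enhancer"),
        ([0.1, 0.1, 0.9, 0.1, 0.1], "active promoter"),
        ([0.1, 0.1, 0.1, 0.1, 0.1], "quiescent"),
    ])
    def test_label_scheme(self, row, expected):
        model = self.make_model([row], self.MARKS)
        assert ch.label_states(model).labels == [expected]


class TestStatesToBed:
    def test_runs_collapse_to_intervals(self):
        path = np.array([0, 0, 1, 1, 1, 0])
        bed = ch.states_to_bed("c", path, ["q", "e"], bin_size=200)
        assert bed["start"].tolist() == [0, 400, 1000]
        assert bed["end"].tolist() == [400, 1000, 1200]
        assert bed["name"].tolist() == ["q", "e", "q"]
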