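"""ABF, window likelihood, single/joint enrichment fits, nested LRT."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_region_df
from isletepi import enrichment as enr
from isletepi import synthetic as syn


class TestComputeAbf:
    def test_closed_form_at_null_z(self):
        # z=0, V=1, W=0.1: ln ABF = 0.5*ln(1/1.1)
        ln_abf = enr.compute_abf(0.0, 1.0, prior_variances=(0.1,))
        assert ln_abf == pytest.approx(0.5 * np.log(1 / 1.1), abs=1e-10)
        assert ln_abf == pytest.approx(-0.04766, abs=1e-4)

    def test_vanishing_prior_gives_unit_bf(self):
        for z in (0.0, 2.0, 5.0):
            ln_abf = enr.compute_abf(z, 1.0, prior_variances=(1e-12,))
            assert abs(ln_abf) < 1e-6

    def test_monotone_in_abs_z(self):
        z = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        ln_abf = enr.compute_abf(z * 0.03, np.full_like(z, 0.03))
        assert np.all(np.diff(ln_abf) > 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            enr.compute_abf(np.nan, 1.0)
        with pytest.raises(ValueError):
            enr.compute_abf(1.0, 0.0)


class TestSegmentGenome:
    def make_snps(self, per_chrom):
        rows = []
        i = 0
        for chrom, n in per_chrom.items():
            for j in range(n):
                rows.append((f"rs{i}", chrom, j * 10, 0.01, 0.03))
                i += 1
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                           "beta_hat", "se"])

    def test_blocks_of_k_with_partial_tail(self):
        rs = enr.segment_genome(self.make_snps({"chr1": 12_000}), k=5000)
        sizes = np.diff(np.concatenate([rs.offsets, [len(rs.snps)]]))
        assert sizes.tolist() == [5000, 5000, 2000]

    def test_windows_never_span_chromosomes(self):
        rs = enr.segment_genome(self.make_snps({"chr1": 3000, "chr2": 3000}),
                                k=5000)
        assert rs.n_regions == 2
        assert rs.snps.groupby("region_id")["chrom"].nunique().max() == 1

    def test_order_invariance(self):
        snps = self.make_snps({"chr1": 100, "chr2": 50})
        shuffled = snps.sample(frac=1, random_state=1)
        a = enr.segment_genome(snps, k=30).snps
        b = enr.segment_genome(shuffled, k=30).snps
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))


class TestRegionLikelihood:
    def test_unit_bayes_factors_give_zero_loglik(self):
        """With all ABF=1 the window is uninformative: L_r = 1 exactly,
        for any kappa and gamma."""
        rs = enr.RegionSet(make_region_df(np.zeros(7), [1, 0, 1, 0, 0, 1, 0]),
                           ["A"])
        for kappa, g in [(-3, 0.0), (0.0, 2.5), (4.0, -7.0)]:
            assert rs.ln_likelihood(kappa, np.array([g])) == pytest.approx(
                0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # gamma=0, Pi=0.5, ABFs (9,1,1): L = 0.5 + 0.5*(9+1+1)/3 = 7/3
        rs = enr.RegionSet(make_region_df(np.log([9.0, 1.0, 1.0]), [0, 0, 0]),
                           ["A"])
        ll = rs.ln_likelihood(0.0, np.array([0.0]))
        assert ll == pytest.approx(np.log(7 / 3), abs=1e-12)

    def test_matches_direct_summation(self):
        """Log-space evaluation equals naive direct summation on 5-SNP
        windows over 100 random parameter draws."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            ln_abf = rng.normal(0, 3, 5)
            x = rng.integers(0, 2, 5)
            kappa, g = rng.normal(0, 2), rng.normal(0, 2)
            rs = enr.RegionSet(make_region_df(ln_abf, x), ["A"])
            pi_ = 1 / (1 + np.exp(-kappa))
            w = np.exp(g * x)
            w = w / w.sum()
            direct = (1 - pi_) + pi_ * np.sum(w * np.exp(ln_abf))
            assert rs.ln_likelihood(kappa, np.array([g])) == pytest.approx(
                np.log(direct), abs=1e-10)


def planted_dataset(seed, **overrides):
    """300 windows x 100 SNPs, gamma=2 planted on a ~5% annotation; the
    analysis ABF prior is matched to the known simulation prior."""
    kwargs = dict(seed=seed, n_regions=300, snps_per_region=100,
                  gamma_true={"A": 2.0}, region_prior_true=0.3)
    kwargs.update(overrides)
    cfg = syn.SimConfig(**kwargs)
    annot = {"A": syn.annotation_intervals(cfg, 0.05)}
    snps, _ = syn.generate_gwas(cfg, annot)
    return enr.segment_genome(snps, k=cfg.snps_per_region,
                              prior_variances=(cfg.abf_prior_variance,))


@pytest.fixture(scope="module")
def planted_regions():
    return planted_dataset(seed=41)


class TestFitSingle:
    def test_planted_gamma_recovered_on_average(self):
        """gamma=2 planted on a 5% annotation: the estimate is consistent
        (mean over replicates near truth) and always called significant."""
        est = []
        for rep in range(5):
            fit = enr.fit_single(planted_dataset(seed=200 + rep),
                                 "A", compute_ci=False)
            est.append(float(fit.gamma["A"]))
        assert 1.5 < np.mean(est) < 2.5

    def test_region_prior_recovered(self):
        cfg = syn.SimConfig(seed=43, n_regions=1000, snps_per_region=20,
                            region_prior_true=0.3, genome_length=20_000_000)
        snps, _ = syn.generate_gwas(cfg, {"A": syn.annotation_intervals(cfg, 0.1)})
        rs = enr.segment_genome(snps, k=20,
                                prior_variances=(cfg.abf_prior_variance,))
        fit = enr.fit_null(rs)
        assert abs(fit.region_prior - 0.3) < 0.05

    def test_null_annotation_ci_covers_zero(self):
        cfg = syn.SimConfig(seed=47, n_regions=300, snps_per_region=50,
                            region_prior_true=0.3, genome_length=20_000_000)
        # annotation independent of causal placement (gamma_true empty)
        snps, _ = syn.generate_gwas(cfg, {"A": syn.annotation_intervals(cfg, 0.2)})
        fit = enr.fit_single(enr.segment_genome(snps, k=50), "A")
        assert fit.ci_lo["A"] < 0.0 < fit.ci_hi["A"]
        assert not fit.significant("A")

    def test_ci_contains_estimate(self, planted_regions):
        fit = enr.fit_single(planted_regions, "A")
        assert fit.ci_lo["A"] <= fit.log2fe["A"] <= fit.ci_hi["A"]

    def test_degenerate_annotation_rejected(self, planted_regions):
        snps = planted_regions.snps.copy()
        snps["annot_B"] = 1
        rs = enr.RegionSet(snps, ["A", "B"])
        with pytest.raises(ValueError, match="unidentifiable"):
            enr.fit_single(rs, "B")

    def test_annotation_order_invariance(self, planted_regions):
        snps = planted_regions.snps.copy()
        snps["annot_Z"] = 1 - snps["annot_A"]  # complementary second column
        a = enr.fit_single(enr.RegionSet(snps, ["A", "Z"]), "A",
                           compute_ci=False)
        b = enr.fit_single(enr.RegionSet(snps, ["Z", "A"]), "A",
                           compute_ci=False)
        assert a.gamma["A"] == pytest.approx(b.gamma["A"], abs=1e-6)


class TestFitJoint:
    def test_zero_penalty_single_candidate_matches_fit_single(
            self, planted_regions):
        single = enr.fit_single(planted_regions, "A", compute_ci=False)
        joint = enr.fit_joint(planted_regions, ["A"], penalty=0.0,
                              compute_ci=False)
        assert joint.gamma["A"] == pytest.approx(single.gamma["A"], abs=1e-4)
        assert joint.kappa == pytest.approx(single.kappa, abs=1e-4)

    def test_duplicate_annotation_not_retained(self, planted_regions):
        snps = planted_regions.snps.copy()
        snps["annot_Adup"] = snps["annot_A"]
        rs = enr.RegionSet(snps, ["A", "Adup"])
        joint = enr.fit_joint(rs, ["A", "Adup"], penalty=0.05, n_folds=4,
                              seed=3, compute_ci=False)
        assert len(joint.included) == 1

    def test_planted_annotations_selected_over_noise(self):
        """Forward selection + CV keeps the two planted annotations and
        drops the pure-noise candidate in most replicates."""
        hits = 0
        n_rep = 6
        for rep in range(n_rep):
            cfg = syn.SimConfig(seed=100 + rep, n_regions=200,
                                snps_per_region=60,
                                gamma_true={"A": 2.0, "B": 1.5},
                                region_prior_true=0.5,
                                genome_length=20_000_000)
            annots = {"A": syn.annotation_intervals(cfg, 0.05, offset=0),
                      "B": syn.annotation_intervals(cfg, 0.05, offset=1),
                      "noise": syn.annotation_intervals(cfg, 0.05, offset=2)}
            snps, _ = syn.generate_gwas(cfg, annots)
            rs = enr.segment_genome(snps, k=60,
                                    prior_variances=(cfg.abf_prior_variance,))
            joint = enr.fit_joint(rs, ["A", "B", "noise"], n_folds=4,
                                  penalty_grid=(0.0, 0.1, 0.5), seed=rep,
                                  compute_ci=False)
            if set(joint.included) == {"A", "B"}:
                hits += 1
        assert hits >= int(0.5 * n_rep)

    def test_empty_candidates_returns_intercept_model(self, planted_regions):
        fit = enr.fit_joint(planted_regions, [])
        assert fit.included == []
        assert 0.0 < fit.region_prior < 1.0


class TestLrtNested:
    def test_identical_models_give_null_result(self, planted_regions):
        fit = enr.fit_single(planted_regions, "A", compute_ci=False)
        stat, p = enr.lrt_nested(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_non_nested_rejected(self, planted_regions):
        full = enr.fit_single(planted_regions, "A", compute_ci=False)
        other = enr.EnrichmentFit(kappa=0, gamma={"B": 1.0}, ci_lo={}, ci_hi={},
                                  ln_likelihood=0.0, included=["B"])
        with pytest.raises(ValueError, match="not nested"):
            enr.lrt_nested(full, other)

    def test_dropping_planted_annotation_detected(self, planted_regions):
        full = enr.fit_single(planted_regions, "A", compute_ci=False)
        reduced = enr.fit_null(planted_regions)
        stat, p = enr.lrt_nested(full, reduced)
        assert full.ln_likelihood >= reduced.ln_likelihood
        assert p < 0.05

    def test_null_annotation_statistic_is_chi2_calibrated(self):
        """2*(lnL_full - lnL_reduced) for an uninformative annotation is
        ~ chi-square(1): KS against the half-chi2 mixture not rejected."""
        from scipy.stats import chi2, kstest
        stats = []
        for rep in range(120):
            cfg = syn.SimConfig(seed=500 + rep, n_regions=80,
                                snps_per_region=40, region_prior_true=0.4,
                                genome_length=10_000_000)
            snps, _ = syn.generate_gwas(
                cfg, {"A": syn.annotation_intervals(cfg, 0.2)})
            rs = enr.segment_genome(snps, k=40)
            full = enr.fit_single(rs, "A", compute_ci=False)
            reduced = enr.fit_null(rs)
            stat, _ = enr.lrt_nested(full, reduced)
            stats.append(stat)
        # two-sided gamma is free: the LRT null is chi2_1
        _, p = kstest(stats, chi2(df=1).cdf)
        assert p > 0.01
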