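"""GRM construction, relatedness pruning, bivariate AI-REML and the
Haseman-Elston oracle."""

import numpy as np
import pandas as pd
import pytest

from bivargwas import greml_rg as gr
from bivargwas import synthetic_cohorts as sc
from bivargwas.io_formats import GenotypePanel, PhenotypeTable, SnpRecord
from tests.conftest import WIDE_WINDOWS


class TestComputeGrm:
    def test_identical_individuals_share_their_diagonal(self):
        rng = np.random.default_rng(61)
        dos = rng.binomial(2, 0.3, size=(10, 50)).astype(float)
        dos[1] = dos[0]
        panel = _panel(dos)
        a = gr.compute_grm(panel).matrix
        assert a[0, 1] == pytest.approx((a[0, 0] + a[1, 1]) / 2, rel=1e-10)

    def test_unrelated_panel_moments(self):
        spec = sc.ArchitectureSpec(n_samples=500, n_snps=5000, seed=62)
        panel = sc.simulate_genotypes(spec)
        a = gr.compute_grm(panel).matrix
        d = np.diag(a)
        assert abs(d.mean() - 1.0) < 3 * d.std() / np.sqrt(len(d))
        # sample-frequency centering makes 1'A1 = 0 exactly, so the mean
        # off-diagonal is -mean(diag)/(n-1), vanishing with n
        off = a[np.triu_indices_from(a, k=1)]
        n = a.shape[0]
        assert off.mean() == pytest.approx(-d.mean() / (n - 1), rel=1e-8)
        assert abs(off.mean()) < 0.01

    def test_single_snp_hand_computed(self):
        dos = np.array([[0.0], [1.0], [2.0]])
        a = gr.compute_grm(_panel(dos), maf_min=0.0).matrix
        # p = 0.5: standardized dosages (-sqrt2, 0, sqrt2)/... = (x-1)/sqrt(.5)
        xs = (dos[:, 0] - 1.0) / np.sqrt(0.5)
        assert np.allclose(a, np.outer(xs, xs), atol=1e-12)

    def test_maf_filter_and_empty_result(self):
        dos = np.zeros((20, 1))
        dos[0, 0] = 1.0  # MAF 1/40 = 0.025
        panel = _panel(dos)
        assert gr.compute_grm(panel, maf_min=0.01).n_snps == 1
        with pytest.raises(ValueError, match="MAF"):
            gr.compute_grm(panel, maf_min=0.1)

    def test_matches_naive_double_loop(self):
        spec = sc.ArchitectureSpec(n_samples=20, n_snps=50, seed=63)
        panel = sc.simulate_genotypes(spec)
        g = gr.compute_grm(panel, maf_min=0.0)
        p = panel.dosages.mean(axis=0) / 2
        keep = np.minimum(p, 1 - p) > 0.0
        x, pk = panel.dosages[:, keep], p[keep]
        naive = np.zeros((20, 20))
        for j in range(20):
            for k in range(20):
                naive[j, k] = np.mean(
                    (x[j] - 2 * pk) * (x[k] - 2 * pk) / (2 * pk * (1 - pk)))
        assert np.abs(g.matrix - naive).max() < 1e-10


def _panel(dosages):
    n, m = dosages.shape
    snps = [SnpRecord(f"s{i}", "1", i + 1, "A", "G") for i in range(m)]
    return GenotypePanel([f"I{i}" for i in range(n)], snps, dosages)


class TestPruneRelatedness:
    def test_unrelated_all_retained(self):
        a = np.eye(4) + 0.01
        g = gr.GRM(list("abcd"), (a + a.T) / 2, 10)
        assert gr.prune_relatedness(g, 0.025) == list("abcd")

    def test_single_related_pair_drops_exactly_one(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        g = gr.GRM(list("abc"), a, 10)
        kept = gr.prune_relatedness(g, 0.025)
        assert len(kept) == 2 and "c" in kept
        assert kept == ["a", "c"]  # tie broken by dropping the later id 'b'

    def test_postcondition_no_retained_pair_at_threshold(self):
        rng = np.random.default_rng(64)
        n = 40
        a = np.eye(n) + rng.normal(0, 0.004, (n, n))
        a = (a + a.T) / 2
        for i, j, v in [(1, 2, 0.3), (2, 3, 0.3), (1, 3, 0.3), (10, 20, 0.05)]:
            a[i, j] = a[j, i] = v
        g = gr.GRM([f"I{i:02d}" for i in range(n)], a, 10)
        kept = gr.prune_relatedness(g, 0.025)
        sub = g.subset(kept).matrix
        np.fill_diagonal(sub, 0.0)
        assert np.abs(sub).max() < 0.025


class TestBivariateReml:
    def test_duplicate_trait_drives_rg_to_one(self, overlap_cohort):
        _, panel, phen, grm = overlap_cohort
        f = phen.frame.copy()
        f["menopause"] = f["menarche"]
        dup = PhenotypeTable(f, phen.traits, phen.covariates)
        vc = gr.bivariate_reml(grm, dup)
        assert vc.r_g == pytest.approx(1.0, abs=1e-3)

    def test_parameter_recovery_full_overlap(self):
        """r_g estimates cover the generating value at the 2-SE level in
        most replicates (small-scale version of the recovery study)."""
        hits, reps = 0, 8
        for seed in range(reps):
            spec = sc.ArchitectureSpec(n_samples=700, n_snps=700,
                                       h2=(0.5, 0.5), r_g=0.5, r_e=0.1,
                                       overlap_fraction=1.0, seed=300 + seed)
            panel = sc.simulate_genotypes(spec)
            phen = sc.simulate_bivariate_phenotypes(panel, spec,
                                                    windows=WIDE_WINDOWS)
            grm = gr.compute_grm(panel)
            vc = gr.bivariate_reml(grm, phen)
            if abs(vc.r_g - 0.5) < 2 * vc.se["r_g"]:
                hits += 1
        assert hits >= reps - 2

    def test_partial_overlap_dense_path(self):
        spec = sc.ArchitectureSpec(n_samples=400, n_snps=500, h2=(0.5, 0.5),
                                   r_g=0.5, r_e=0.0, overlap_fraction=0.5,
                                   seed=65)
        panel = sc.simulate_genotypes(spec)
        phen = sc.simulate_bivariate_phenotypes(panel, spec,
                                                windows=WIDE_WINDOWS)
        grm = gr.compute_grm(panel)
        vc = gr.bivariate_reml(grm, phen)
        assert vc.method.endswith("(dense)")
        assert np.isfinite(vc.r_g) and abs(vc.r_g) <= 1 + 1e-8
        assert vc.se["r_g"] > 0

    def test_affine_invariance_of_rg(self, overlap_cohort):
        _, panel, phen, grm = overlap_cohort
        vc = gr.bivariate_reml(grm, phen)
        f = phen.frame.copy()
        f["menarche"] = 3.0 * f["menarche"] - 7.0
        f["menopause"] = 0.25 * f["menopause"] + 100.0
        scaled = PhenotypeTable(f, phen.traits, phen.covariates)
        vc2 = gr.bivariate_reml(grm, scaled)
        assert vc2.r_g == pytest.approx(vc.r_g, abs=1e-6)

    def test_pc_adjustment_changes_rg_little(self, overlap_cohort):
        """On stratification-free data, adding 10 genotype PCs as covariates
        moves r_g by far less than its SE."""
        _, panel, phen, grm = overlap_cohort
        vc = gr.bivariate_reml(grm, phen)
        xs = sc.standardize_dosages(panel.dosages)
        u, s, _ = np.linalg.svd(xs, full_matrices=False)
        f = phen.frame.copy()
        pcs = [f"pc{i}" for i in range(10)]
        for i, name in enumerate(pcs):
            f[name] = u[:, i]
        withpc = PhenotypeTable(f, phen.traits, phen.covariates + tuple(pcs))
        vc2 = gr.bivariate_reml(grm, withpc, covariates=tuple(pcs))
        assert abs(vc2.r_g - vc.r_g) < 2 * vc.se["r_g"]

    def test_requires_minimum_sample(self, overlap_cohort):
        _, panel, phen, grm = overlap_cohort
        f = phen.frame.iloc[:30]
        small = PhenotypeTable(f.copy(), phen.traits, phen.covariates)
        with pytest.raises(ValueError, match="non-missing"):
            gr.bivariate_reml(grm, small)


class TestHeRegression:
    def test_noiseless_heritability_recovered(self):
        spec = sc.ArchitectureSpec(n_samples=500, n_snps=400, h2=(1.0, 1.0),
                                   r_g=0.5, r_e=0.0, overlap_fraction=1.0,
                                   seed=66)
        panel = sc.simulate_genotypes(spec)
        phen = sc.simulate_bivariate_phenotypes(panel, spec,
                                                windows=WIDE_WINDOWS)
        he = gr.he_regression(gr.compute_grm(panel), phen)
        assert abs(he.vg1 - 1.0) < 3 * max(he.se["vg1"], 0.05)

    def test_zero_rg_cross_slope_near_zero(self):
        spec = sc.ArchitectureSpec(n_samples=600, n_snps=600, h2=(0.5, 0.5),
                                   r_g=0.0, r_e=0.0, overlap_fraction=1.0,
                                   seed=67)
        panel = sc.simulate_genotypes(spec)
        phen = sc.simulate_bivariate_phenotypes(panel, spec,
                                                windows=WIDE_WINDOWS)
        he = gr.he_regression(gr.compute_grm(panel), phen)
        assert abs(he.cg) < 3 * max(he.se["cg"], 0.02)

    def test_reml_and_he_track_each_other(self):
        """Across replicate datasets the two estimators of r_g co-vary."""
        reml_est, he_est = [], []
        for seed in range(10):
            spec = sc.ArchitectureSpec(n_samples=500, n_snps=500,
                                       h2=(0.5, 0.5), r_g=0.5, r_e=0.1,
                                       overlap_fraction=1.0, seed=400 + seed)
            panel = sc.simulate_genotypes(spec)
            phen = sc.simulate_bivariate_phenotypes(panel, spec,
                                                    windows=WIDE_WINDOWS)
            grm = gr.compute_grm(panel)
            reml_est.append(gr.bivariate_reml(grm, phen).r_g)
            he_est.append(gr.he_regression(grm, phen).r_g)
        r = np.corrcoef(reml_est, he_est)[0, 1]
        assert r > 0.8
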