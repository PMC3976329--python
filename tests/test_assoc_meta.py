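"""Association, genomic control and inverse-variance meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from bivargwas import assoc_meta as am
from bivargwas import synthetic_cohorts as sc
from bivargwas.io_formats import PhenotypeTable, SummaryStats


def _phen(panel, y, covs=None):
    frame = pd.DataFrame({"trait": y}, index=pd.Index(panel.sample_ids,
                                                      name="IID"))
    covariates = ()
    if covs:
        for name, vals in covs.items():
            frame[name] = vals
        covariates = tuple(covs)
    return PhenotypeTable(frame, ("trait",), covariates)


class TestRunGwas:
    def test_noiseless_effect_recovered_exactly(self, small_cohort):
        _, panel, _ = small_cohort
        y = 0.5 * panel.dosages[:, 3]
        stats = am.run_gwas(panel, _phen(panel, y), "trait")
        row = stats.table.iloc[3]
        assert row["beta"] == pytest.approx(0.5, abs=1e-10)
        assert row["p"] < 1e-100

    def test_null_type_one_error_calibrated(self):
        spec = sc.ArchitectureSpec(n_samples=400, n_snps=1000, seed=21)
        panel = sc.simulate_genotypes(spec)
        rng = np.random.default_rng(22)
        y = rng.standard_normal(panel.n_samples)  # pure noise phenotype
        stats = am.run_gwas(panel, _phen(panel, y), "trait")
        frac = (stats.table["p"] < 0.05).mean()
        # 99% binomial CI around 0.05 at 1000 SNPs
        assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 1000)

    def test_collinear_covariate_gives_missing_statistic(self, small_cohort):
        _, panel, _ = small_cohort
        rng = np.random.default_rng(23)
        y = rng.standard_normal(panel.n_samples)
        phen = _phen(panel, y, covs={"dup": panel.dosages[:, 0]})
        stats = am.run_gwas(panel, phen, "trait", covariates=("dup",))
        # SNP 0 is collinear with its own covariate: statistic missing, others fine
        assert stats.table.loc[stats.table["snp"] == "snp000000"].empty
        assert len(stats) == panel.n_snps - 1

    def test_planted_beta_unbiased(self):
        spec = sc.ArchitectureSpec(n_samples=2000, n_snps=200, h2=(0, 0),
                                   r_e=0.0, overlap_fraction=1.0, seed=24,
                                   planted_effects=((5, 0.2, 0.0),))
        panel = sc.simulate_genotypes(spec)
        phen = sc.simulate_bivariate_phenotypes(panel, spec)
        stats = am.run_gwas(panel, phen, "menarche")
        row = stats.table.iloc[5]
        # planted on the standardized scale; trait units carry SD 1.5
        xs_sd = panel.dosages[:, 5].std()
        expected = 0.2 * 1.5 / xs_sd
        assert row["beta"] == pytest.approx(expected, abs=3 * row["se"])

    def test_too_few_rows_rejected(self, small_cohort):
        _, panel, _ = small_cohort
        y = np.full(panel.n_samples, np.nan)
        y[:5] = 1.0
        with pytest.raises(ValueError, match="non-missing"):
            am.run_gwas(panel, _phen(panel, y), "trait")


class TestGenomicControl:
    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(31)
        z = rng.standard_normal(100_000)
        stats = _stats_from_z(z)
        lam, _ = am.genomic_control(stats)
        assert 0.97 < lam < 1.03

    def test_scale_equivariance(self):
        rng = np.random.default_rng(32)
        z = rng.standard_normal(5000)
        lam1, _ = am.genomic_control(_stats_from_z(z))
        lam2, adj = am.genomic_control(_stats_from_z(z * np.sqrt(2)))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-10)
        # adjusted z equals original z (deflation undoes the inflation)
        expect = z * np.sqrt(2) / np.sqrt(lam2)
        assert np.allclose(adj.table["z"].to_numpy(), expect, atol=1e-10)

    def test_no_deflation_below_one(self):
        rng = np.random.default_rng(33)
        z = rng.standard_normal(2000) * 0.8  # lambda ~ 0.64
        stats = _stats_from_z(z)
        lam, adj = am.genomic_control(stats)
        assert lam < 1
        assert adj is stats  # unchanged object

    def test_refuses_small_input(self):
        stats = _stats_from_z(np.ones(50))
        with pytest.raises(ValueError, match="100"):
            am.genomic_control(stats)


def _stats_from_z(z, ea="A", oa="G", eaf=None, chrom="1"):
    n = len(z)
    se = np.full(n, 0.01)
    return SummaryStats.from_frame(pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "chrom": chrom, "pos": np.arange(1, n + 1),
        "ea": ea, "oa": oa,
        "eaf": 0.3 if eaf is None else eaf,
        "beta": z * se, "se": se, "n": 1000.0,
    }))


class TestMetaFixedEffects:
    def test_two_identical_studies_halve_the_variance(self):
        s = _stats_from_z(np.array([2.0, -1.0]))
        meta = am.meta_fixed_effects([s, s])
        t = meta.stats.table
        base = s.table.set_index("snp")
        for snp in ("rs0", "rs1"):
            row = t.loc[t["snp"] == snp].iloc[0]
            assert row["beta"] == pytest.approx(base.loc[snp, "beta"])
            assert row["se"] == pytest.approx(base.loc[snp, "se"] / np.sqrt(2))

    def test_single_study_is_identity(self):
        s = _stats_from_z(np.array([1.5, 0.3, -2.2]))
        meta = am.meta_fixed_effects([s])
        assert np.allclose(meta.stats.table["beta"], s.table["beta"])
        assert np.allclose(meta.stats.table["se"], s.table["se"])
        assert (meta.n_studies == 1).all()

    def test_swapped_alleles_flip_sign(self):
        s1 = _stats_from_z(np.array([2.0]))
        s2 = _stats_from_z(np.array([-2.0]), ea="G", oa="A", eaf=0.7)
        meta = am.meta_fixed_effects([s1, s2])
        row = meta.stats.table.iloc[0]
        # after flipping study 2 the effects agree: same beta, se/sqrt(2)
        assert row["beta"] == pytest.approx(0.02)
        assert row["se"] == pytest.approx(0.01 / np.sqrt(2))
        assert meta.q_stat.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(41)
        s1 = _stats_from_z(rng.standard_normal(20))
        s2 = _stats_from_z(rng.standard_normal(20))
        a = am.meta_fixed_effects([s1, s2]).stats.table
        b = am.meta_fixed_effects([s2, s1]).stats.table
        m = a.merge(b, on="snp", suffixes=("_a", "_b"))
        assert np.allclose(m["beta_a"], m["beta_b"], atol=1e-12)
        assert np.allclose(m["se_a"], m["se_b"], atol=1e-12)

    def test_ambiguous_palindromic_excluded(self):
        s1 = _stats_from_z(np.array([2.0]), ea="A", oa="T", eaf=0.5)
        s2 = _stats_from_z(np.array([2.0]), ea="A", oa="T", eaf=0.5)
        meta = am.meta_fixed_effects([s1, s2])
        # a strand-ambiguous palindromic SNP cannot be oriented in any
        # study, so the SNP drops out of the combined set entirely
        assert meta.n_excluded == 2
        assert len(meta.stats) == 0

    def test_coverage_of_true_effect_across_studies(self):
        """Three studies with a common effect: the combined estimate covers
        the truth at the nominal 2-SE rate."""
        rng = np.random.default_rng(42)
        truth, se = 0.1, 0.05
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            studies = []
            for _ in range(3):
                b = truth + rng.standard_normal() * se
                studies.append(SummaryStats.from_frame(pd.DataFrame({
                    "snp": ["rs0"], "chrom": "1", "pos": [1], "ea": "A",
                    "oa": "G", "eaf": 0.3, "beta": [b], "se": [se], "n": 100.0,
                })))
            row = am.meta_fixed_effects(studies).stats.table.iloc[0]
            if abs(row["beta"] - truth) < 2 * row["se"]:
                hits += 1
        assert hits / n_rep >= 0.93
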