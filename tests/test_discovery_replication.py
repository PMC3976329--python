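"""Lead selection, LD proxies, staged combination, sign tests,
lifespan classification and report rendering."""

import numpy as np
import pandas as pd
import pytest

from bivargwas import discovery_replication as dr
from bivargwas import synthetic_cohorts as sc
from bivargwas.assoc_meta import meta_fixed_effects
from bivargwas.io_formats import SummaryStats
from bivargwas.lifespan import EffectClass, UnclassifiableEffectError


def _elc_frame(ps, positions=None, chrom="1"):
    n = len(ps)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "chrom": chrom,
        "pos": positions if positions is not None
        else np.arange(n) * 5_000_000 + 1,
        "p": ps,
    })


class TestSelectHits:
    def test_threshold_behaviour_on_reported_pvalues(self):
        """Six independent signals spanning the suggestive range: the strict
        1e-7 rule advances three, a relaxed 5e-7 rule advances all six."""
        ps = [4.13e-10, 1.63e-9, 9.82e-8, 1.17e-7, 1.24e-7, 3.27e-7]
        df = _elc_frame(ps)
        assert len(dr.select_hits(df, threshold=1e-7)) == 3
        assert len(dr.select_hits(df, threshold=5e-7)) == 6

    def test_nearby_hits_thinned_to_one_lead(self):
        df = _elc_frame([1e-9, 1e-8], positions=[1_000_000, 1_500_000])
        leads = dr.select_hits(df, threshold=1e-7)
        assert leads["snp"].tolist() == ["rs0"]  # 500 kb apart -> one lead

    def test_empty_results(self):
        assert len(dr.select_hits(_elc_frame([]), 1e-7)) == 0


@pytest.fixture(scope="module")
def ld_panel():
    spec = sc.ArchitectureSpec(n_samples=6000, n_snps=10,
                               maf_range=(0.3, 0.4), seed=71,
                               ld_blocks=(5, 0.95), snp_spacing_bp=50_000)
    return sc.simulate_genotypes(spec)


class TestFindLdProxies:
    def test_lead_excluded_and_block_recovered(self, ld_panel):
        proxies = dr.find_ld_proxies(ld_panel, "snp000000", r2_min=0.8)
        names = [s for s, _ in proxies]
        assert "snp000000" not in names
        assert set(names) <= {f"snp{i:06d}" for i in range(1, 5)}
        # generating dosage correlation 0.95 -> r2 about 0.9025
        top_r2 = proxies[0][1]
        assert top_r2 == pytest.approx(0.9025, abs=0.03)

    def test_independent_snp_not_a_proxy(self, ld_panel):
        proxies = dr.find_ld_proxies(ld_panel, "snp000000", r2_min=0.8)
        assert all(not s.startswith("snp00000" + str(i))
                   for s, _ in proxies for i in (5, 6, 7, 8, 9))

    def test_monomorphic_lead_rejected(self, ld_panel):
        panel = sc.simulate_genotypes(
            sc.ArchitectureSpec(n_samples=50, n_snps=3, seed=72))
        panel.dosages[:, 0] = 2.0
        with pytest.raises(ValueError, match="monomorphic"):
            dr.find_ld_proxies(panel, "snp000000")


def _single_snp_stats(beta, se, ea="A"):
    oa = "G" if ea == "A" else "A"
    return SummaryStats.from_frame(pd.DataFrame({
        "snp": ["rs0"], "chrom": "1", "pos": [1], "ea": ea, "oa": oa,
        "eaf": 0.3 if ea == "A" else 0.7, "beta": [beta], "se": [se],
        "n": 100.0,
    }))


class TestCombineStages:
    def test_identical_stages_halve_variance(self):
        a = _single_snp_stats(0.2, 0.1)
        comb, missing = dr.combine_stages(a, a)
        assert comb.table["se"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))
        assert missing == []

    def test_opposite_equal_effects_cancel(self):
        comb, _ = dr.combine_stages(_single_snp_stats(0.2, 0.1),
                                    _single_snp_stats(-0.2, 0.1))
        # beta cancels; validation drops the z-inconsistency-free zero row?
        row = comb.table.iloc[0]
        assert row["beta"] == pytest.approx(0.0, abs=1e-15)

    def test_missing_replication_flagged(self):
        a = _single_snp_stats(0.2, 0.1)
        b = _single_snp_stats(0.2, 0.1)
        b.table["snp"] = ["other"]
        comb, missing = dr.combine_stages(a, b)
        assert set(missing) == {"rs0", "other"}

    def test_equals_meta_fixed_effects_exactly(self):
        rng = np.random.default_rng(73)
        z = rng.standard_normal(50)
        from tests.test_assoc_meta import _stats_from_z
        a, b = _stats_from_z(z), _stats_from_z(z + 0.3)
        comb, _ = dr.combine_stages(a, b)
        meta = meta_fixed_effects([a, b])
        assert np.allclose(comb.table["beta"], meta.stats.table["beta"])
        assert np.allclose(comb.table["se"], meta.stats.table["se"])


class TestDirectionConsistency:
    def _hits(self, signs):
        hits = []
        for i, (d, r) in enumerate(signs):
            hits.append(dr.HitRecord(
                snp_id=f"rs{i}", chrom="1", pos=i + 1, p_bivariate=1e-8,
                discovery={"menarche": dr.StageStats(d, 0.1, 0.5, 100)},
                replication={"menarche": dr.StageStats(r, 0.1, 0.5, 100)},
                combined={},
            ))
        return hits

    def test_eleven_of_sixteen(self):
        from scipy.stats import binomtest
        signs = [(1, 1)] * 11 + [(1, -1)] * 5
        n_cons, n_tot, p = dr.direction_consistency(self._hits(signs),
                                                    "menarche")
        assert (n_cons, n_tot) == (11, 16)
        assert p == pytest.approx(binomtest(11, 16, 0.5).pvalue)

    def test_perfect_consistency_closed_form(self):
        signs = [(1, 1)] * 16
        _, _, p = dr.direction_consistency(self._hits(signs), "menarche")
        assert p == pytest.approx(2 * 0.5 ** 16 * 1, rel=1e-10)  # 2^-15

    def test_even_split_gives_p_one(self):
        signs = [(1, 1)] * 8 + [(1, -1)] * 8
        _, _, p = dr.direction_consistency(self._hits(signs), "menarche")
        assert p == pytest.approx(1.0)

    def test_zero_beta_excluded(self):
        signs = [(1, 1), (0, 1)]
        n_cons, n_tot, _ = dr.direction_consistency(self._hits(signs),
                                                    "menarche")
        assert (n_cons, n_tot) == (1, 1)


class TestClassifyEffect:
    def _hit(self, b1, b2):
        return dr.HitRecord(
            snp_id="rs0", chrom="1", pos=1, p_bivariate=1e-8,
            discovery={}, replication={},
            combined={"menarche": dr.StageStats(b1, 0.1, 0.5, 10),
                      "menopause": dr.StageStats(b2, 0.1, 0.5, 10)},
        )

    @pytest.mark.parametrize("b1,b2,expected", [
        (0.1, 0.1, EffectClass.RIGHT_SHIFT),
        (-0.1, -0.1, EffectClass.LEFT_SHIFT),
        (-0.1, 0.1, EffectClass.LIFESPAN_INCREASE),
        (0.1, -0.1, EffectClass.LIFESPAN_DECREASE),
    ])
    def test_sign_patterns(self, b1, b2, expected):
        assert dr.classify_effect(self._hit(b1, b2)) is expected

    def test_zero_beta_unclassifiable(self):
        with pytest.raises(UnclassifiableEffectError):
            dr.classify_effect(self._hit(0.0, 0.1))


@pytest.fixture(scope="module")
def result():
    n = 3000
    b = 7.0 / np.sqrt(n * 0.68)
    spec = sc.ArchitectureSpec(
        n_samples=n, n_snps=1000, seed=88,
        planted_effects=((50, b, b), (500, -b, b)))
    return spec, dr.run_synthetic_pipeline(spec, replication_n=1500,
                                           b_calibration=50_000)


class TestPipeline:
    def test_planted_snps_recovered_with_their_classes(self, result):
        spec, res = result
        found = {h.snp_id: h for h in res.hits}
        truth = res.truth.set_index("snp")
        for snp in truth.index:
            assert snp in found
            assert found[snp].effect_class.value == truth.loc[snp, "class"]

    def test_report_rendering_deterministic(self, result, tmp_path):
        spec, res = result
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            dr.render_report(res.hits, res.calibration, d,
                             config={"seed": spec.seed})
        for name in ("leads.tsv", "staged_results.tsv", "calibration.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_empty_hit_set_renders_headers(self, tmp_path):
        paths = dr.render_report([], None, tmp_path)
        lines = paths["leads"].read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("snp\t")

    def test_truth_table_carries_planted_classes(self, result):
        _, res = result
        assert res.truth["class"].tolist() == ["right_shift",
                                               "lifespan_increase"]
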