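"""Association scans against closed-form regression, plus pleiotropy assembly."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from behavarch import gwas
from behavarch.errors import InsufficientDataError
from behavarch.simulate import (
    PanelSimConfig,
    TraitArchitecture,
    gen_genotypes,
    gen_phenotypes,
)
from helpers import panel_from_dosages


def series_for(panel, values):
    return pd.Series(np.asarray(values, dtype=float), index=panel.line_ids, name="y")


class TestAssocScan:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        panel = panel_from_dosages(dos)
        y = series_for(panel, 2.0 * dos[:, 2])
        res = gwas.assoc_scan(panel, y)
        assert res.table.loc["s2", "BETA"] == pytest.approx(2.0, abs=1e-10)
        assert res.table.loc["s2", "P"] < 1e-30

    def test_six_line_toy_matches_least_squares(self):
        dos = np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [2.0]])
        panel = panel_from_dosages(dos)
        y = series_for(panel, [1, 2, 2, 3, 3, 5])
        res = gwas.assoc_scan(panel, y)
        # hand OLS: Sxx = 4, Sxy = 5 -> beta = 1.25
        assert res.table.loc["s0", "BETA"] == pytest.approx(1.25, abs=1e-12)
        lr = st.linregress(dos[:, 0], y.to_numpy())
        assert res.table.loc["s0", "BETA"] == pytest.approx(lr.slope, abs=1e-10)
        assert res.table.loc["s0", "SE"] == pytest.approx(lr.stderr, abs=1e-10)
        assert res.table.loc["s0", "P"] == pytest.approx(lr.pvalue, rel=1e-8)

    def test_agrees_with_linregress_across_random_panel(self):
        rng = np.random.default_rng(3)
        cfg = PanelSimConfig(n_lines=80, n_snps=40, seed=3)
        panel = gen_genotypes(cfg)
        y = series_for(panel, rng.standard_normal(80))
        res = gwas.assoc_scan(panel, y)
        for j, sid in enumerate(panel.snp_ids):
            if not res.table.loc[sid, "testable"]:
                continue
            lr = st.linregress(panel.dosages[:, j], y.to_numpy())
            assert res.table.loc[sid, "BETA"] == pytest.approx(lr.slope, abs=1e-10)
            assert res.table.loc[sid, "SE"] == pytest.approx(lr.stderr, abs=1e-10)

    def test_missing_dosages_dropped_per_snp(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.5, size=(40, 3)).astype(float)
        dos[:10, 1] = np.nan
        panel = panel_from_dosages(dos)
        yv = rng.standard_normal(40)
        res = gwas.assoc_scan(panel, series_for(panel, yv))
        lr = st.linregress(dos[10:, 1], yv[10:])
        assert res.table.loc["s1", "NMISS"] == 30
        assert res.table.loc["s1", "BETA"] == pytest.approx(lr.slope, abs=1e-10)

    def test_monomorphic_snp_flagged_not_fatal(self):
        dos = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0], [0.0, 1.0]])
        panel = panel_from_dosages(dos)
        res = gwas.assoc_scan(panel, series_for(panel, [1, 2, 3, 4]))
        assert not res.table.loc["s0", "testable"]
        assert np.isnan(res.table.loc["s0", "BETA"])
        assert res.table.loc["s1", "testable"]

    def test_null_p_values_are_uniform(self):
        cfg = PanelSimConfig(n_lines=200, n_snps=5000, seed=5)
        panel = gen_genotypes(cfg)
        rng = np.random.default_rng(6)
        y = series_for(panel, rng.standard_normal(200))
        res = gwas.assoc_scan(panel, y)
        p = res.table.loc[res.table["testable"], "P"]
        assert st.kstest(p, "uniform").pvalue > 0.001

    def test_too_few_lines_rejected(self):
        panel = panel_from_dosages(np.array([[0.0], [2.0]]))
        with pytest.raises(InsufficientDataError):
            gwas.assoc_scan(panel, series_for(panel, [1, 2]))


class TestHitsAndPower:
    def test_strict_threshold_boundary(self):
        table = pd.DataFrame(
            {"P": [5e-6, 4.9e-6, np.nan]},
            index=pd.Index(["a", "b", "c"], name="SNP"),
        )
        res = gwas.AssocResult("t", table, 10)
        assert gwas.significant_hits(res) == {"b"}

    def test_recovers_strong_causal_snps(self):
        causal = np.arange(10)
        cfg = PanelSimConfig(n_lines=1000, n_snps=1000, seed=8)
        panel = gen_genotypes(cfg)
        # equal per-locus variance contributions (~6% each at h2 = 0.6)
        p = panel.allele_freqs()[causal]
        betas = 1.0 / np.sqrt(4.0 * p * (1.0 - p))
        cfg.traits = [TraitArchitecture("t", causal, betas=betas, h2=0.6)]
        phen = gen_phenotypes(panel, cfg)
        res = gwas.assoc_scan(panel, phen["t"])
        hits = gwas.significant_hits(res, 5e-6)
        causal_ids = {panel.snp_ids[i] for i in causal}
        assert len(hits & causal_ids) >= 8


class TestPleiotropyAndEffectMatrix:
    def test_disjoint_hits_give_empty_incidence(self):
        pm = gwas.build_pleiotropy_matrix({"a": {"s1"}, "b": {"s2"}})
        assert pm.incidence.empty

    def test_shared_snps_counted(self):
        hits = {"a": {"s1", "s2", "s3", "s9"}, "b": {"s1", "s2", "s3", "s8"}}
        pm = gwas.build_pleiotropy_matrix(hits)
        assert pm.incidence.shape == (3, 2)
        assert (pm.incidence.sum(axis=1) == 2).all()
        assert (pm.snp_trait_counts == 2).all()

    def test_gene_annotation_rollup(self):
        hits = {"a": {"s1", "s2"}, "b": {"s1", "s2"}}
        ann = {"s1": "gene1", "s2": "gene1", "zzz": "gene9"}
        pm = gwas.build_pleiotropy_matrix(hits, ann)
        assert pm.gene_multitrait_counts.loc["gene1"] == 2
        assert pm.unmatched_annotation_ids == ["zzz"]

    def test_effect_matrix_mirrors_scans(self, small_panel):
        panel, phen = small_panel
        scan = gwas.assoc_scan(panel, phen["t0"])
        hits = gwas.significant_hits(scan, 1e-3)
        assert len(hits) >= 1
        em = gwas.build_effect_matrix({"t0": scan, "copy": scan},
                                      {"t0": hits, "copy": hits})
        assert list(em.betas.index) == sorted(hits)
        pd.testing.assert_series_equal(
            em.betas["t0"], em.betas["copy"], check_names=False
        )
        for sid in em.betas.index:
            assert em.betas.loc[sid, "t0"] == scan.table.loc[sid, "BETA"]

    def test_missing_scan_rejected(self):
        with pytest.raises(Exception):
            gwas.build_effect_matrix({}, {"a": {"s1"}})


class TestTraitCorrelations:
    def make_matrix(self, data):
        betas = pd.DataFrame(data)
        return gwas.EffectMatrix(betas=betas, hits={c: set(betas.index) for c in betas})

    def test_duplicate_and_negated_columns(self):
        v = [1.0, 3.0, 2.0, 5.0, 4.0]
        em = self.make_matrix({"a": v, "b": v, "c": [-x for x in v]})
        corr = gwas.trait_correlation_structure(em)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_matches_scipy_spearman_with_ties(self):
        a = [1.0, 2.0, 2.0, 4.0, 5.0]
        b = [2.0, 1.0, 4.0, 4.0, 3.0]
        em = self.make_matrix({"a": a, "b": b})
        corr = gwas.trait_correlation_structure(em)
        assert corr.loc["a", "b"] == pytest.approx(
            st.spearmanr(a, b).statistic, abs=1e-12
        )

    def test_sparse_pair_left_undefined(self):
        em = self.make_matrix(
            {"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, np.nan, 1.0, 2.0]}
        )
        corr = gwas.trait_correlation_structure(em)
        assert np.isnan(corr.loc["a", "b"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        em1 = self.make_matrix({"a": a, "b": b})
        em2 = self.make_matrix({"a": np.exp(a), "b": b})
        c1 = gwas.trait_correlation_structure(em1)
        c2 = gwas.trait_correlation_structure(em2)
        assert c1.loc["a", "b"] == pytest.approx(c2.loc["a", "b"], abs=1e-12)


class TestSampleSizePvalue:
    def test_constant_sample_size_flagged(self, small_panel):
        panel, phen = small_panel
        scan = gwas.assoc_scan(panel, phen["t0"])
        hits = gwas.significant_hits(scan, 1e-2)
        out = gwas.samplesize_pvalue_correlation(
            {"a": scan, "b": scan}, {"a": hits, "b": hits}
        )
        assert not out.defined

    def test_null_correlation_is_weak(self):
        rng = np.random.default_rng(2)
        scans, hits = {}, {}
        for t in range(4):
            n = 60 + 40 * t
            cfg = PanelSimConfig(n_lines=n, n_snps=400, seed=30 + t)
            panel = gen_genotypes(cfg)
            y = pd.Series(rng.standard_normal(n), index=panel.line_ids)
            scan = gwas.assoc_scan(panel, y, trait=f"t{t}")
            scans[f"t{t}"] = scan
            # pool the nominally smallest P-values per trait
            hits[f"t{t}"] = set(scan.table["P"].nsmallest(25).index)
        out = gwas.samplesize_pvalue_correlation(scans, hits)
        assert out.defined
        assert abs(out.rho) < 0.35
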