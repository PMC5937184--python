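"""GRM arithmetic oracles and GREML estimation properties."""

import numpy as np
import pandas as pd
import pytest

from behavarch import heritability as her
from behavarch.errors import DegenerateInputError, EmptyPanelError, UnknownIdError
from behavarch.panel import GenotypePanel
from behavarch.simulate import (
    PanelSimConfig,
    TraitArchitecture,
    gen_genotypes,
    gen_phenotypes,
)
from helpers import panel_from_dosages


class TestMafFilter:
    def test_counts_by_hand(self):
        # 10 SNPs over 10 outbred lines; 3 SNPs given MAF below the cutoff
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(10, 10)).astype(float)
        dos[:, 0] = 0.0
        dos[:, 1] = [2.0] + [0.0] * 9  # freq 0.1 -> kept at threshold 0.05
        dos[:, 2] = 2.0
        panel = panel_from_dosages(dos)
        kept = her.filter_maf(panel, 0.05)
        assert kept.n_snps == 8  # two monomorphic SNPs removed

    def test_boundary_frequency_removed(self):
        dos = np.zeros((100, 2))
        dos[0, 0] = 2.0  # freq exactly 0.01
        dos[:50, 1] = 2.0
        panel = panel_from_dosages(dos)
        kept = her.filter_maf(panel, 0.01)
        assert list(kept.snp_ids) == ["s1"]

    def test_all_monomorphic_raises(self):
        panel = panel_from_dosages(np.zeros((5, 3)))
        with pytest.raises(EmptyPanelError):
            her.filter_maf(panel, 0.01)


class TestGrm:
    def test_toy_matrix_matches_hand_computation(self, toy_outbred_panel):
        # dosages [[0,2],[2,0],[2,2]], p = 2/3 per SNP, denom 2p(1-p) = 4/9;
        # standardized rows: l1 (-2, 1), l2 (1, -2), l3 (1, 1); A = WW'/2
        grm = her.build_grm(toy_outbred_panel)
        expected = np.array(
            [[2.5, -2.0, -0.5], [-2.0, 2.5, -0.5], [-0.5, -0.5, 1.0]]
        )
        np.testing.assert_allclose(grm.matrix, expected, atol=1e-12)
        assert grm.n_snps_used == 2

    def test_identical_lines_share_all_entries(self):
        dos = np.array([[0.0, 2.0, 2.0], [0.0, 2.0, 2.0], [2.0, 0.0, 0.0]])
        grm = her.build_grm(panel_from_dosages(dos))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])
        assert grm.matrix[0, 0] == pytest.approx(grm.matrix[1, 1])

    def test_mean_diagonal_near_one_under_hardy_weinberg(self):
        cfg = PanelSimConfig(n_lines=50, n_snps=2000, inbred=False, seed=3)
        panel = gen_genotypes(cfg)
        panel = her.filter_maf(panel, 0.01)
        grm = her.build_grm(panel)
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.1

    def test_inbred_scaling_restores_unit_diagonal(self):
        cfg = PanelSimConfig(n_lines=60, n_snps=2000, inbred=True, seed=4)
        panel = her.filter_maf(gen_genotypes(cfg), 0.01)
        assert abs(np.diag(her.build_grm(panel).matrix).mean() - 1.0) < 0.1
        # forcing the outbred denominator on {0,2} dosages doubles it
        assert abs(
            np.diag(her.build_grm(panel, inbred=False).matrix).mean() - 2.0
        ) < 0.2

    def test_symmetry_and_permutation_congruence(self):
        cfg = PanelSimConfig(n_lines=20, n_snps=200, seed=5)
        panel = her.filter_maf(gen_genotypes(cfg), 0.01)
        grm = her.build_grm(panel)
        np.testing.assert_array_equal(grm.matrix, grm.matrix.T)
        perm = np.random.default_rng(0).permutation(panel.n_lines)
        permuted = panel.subset_lines([panel.line_ids[i] for i in perm])
        grm_p = her.build_grm(permuted)
        np.testing.assert_allclose(
            grm_p.matrix, grm.matrix[np.ix_(perm, perm)], atol=1e-12
        )

    def test_monomorphic_snp_rejected(self):
        dos = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        with pytest.raises(DegenerateInputError):
            her.build_grm(panel_from_dosages(dos))


def simulated_fit(h2, seed, n_lines=500, n_snps=2000, n_causal=50):
    causal = np.arange(n_causal)
    cfg = PanelSimConfig(
        n_lines=n_lines, n_snps=n_snps,
        traits=[TraitArchitecture("t", causal, h2=h2)], seed=seed,
    )
    panel = gen_genotypes(cfg)
    phen = gen_phenotypes(panel, cfg)
    grm = her.build_grm(her.filter_maf(panel, 0.01))
    return panel, phen, her.greml_fit(grm, phen["t"])


class TestGreml:
    def test_null_trait_estimates_near_zero(self):
        _, _, res = simulated_fit(0.0, seed=1)
        assert res.heritability < 0.15
        assert res.p_value > 0.2

    def test_recovers_moderate_heritability(self):
        # single-fit SE is ~0.1 at this size; averaging four seeded
        # replicates brings the Monte-Carlo error inside the band
        fits = [simulated_fit(0.5, seed=s, n_lines=1000, n_snps=5000)[2]
                for s in (2, 3, 4, 5)]
        mean_h2 = np.mean([f.heritability for f in fits])
        assert 0.4 <= mean_h2 <= 0.6
        for res in fits:
            assert res.converged
            assert res.vg >= 0 and res.ve >= 0
            assert res.vp == res.vg + res.ve

    def test_noiseless_genetic_value_hits_upper_boundary(self):
        cfg = PanelSimConfig(
            n_lines=200, n_snps=500,
            traits=[TraitArchitecture("t", np.arange(30), h2=0.5)], seed=6,
        )
        panel = gen_genotypes(cfg)
        phen = gen_phenotypes(panel, cfg)
        g = phen.attrs["genetic_values"]["t"]  # zero residual variance
        # GRM over exactly the causal loci: the genetic value lies in its
        # span, so Ve is driven to the lower boundary
        causal_ids = [panel.snp_ids[i] for i in range(30)]
        res = her.greml_on_snp_subset(panel, causal_ids, g.to_numpy())
        assert res.heritability > 0.95
        assert res.boundary

    def test_em_iterations_increase_likelihood(self):
        # pure-EM run (no AI steps): REML log-likelihood is monotone
        _, phen, _ = simulated_fit(0.4, seed=7, n_lines=120, n_snps=400)
        cfg = PanelSimConfig(
            n_lines=120, n_snps=400,
            traits=[TraitArchitecture("t", np.arange(50), h2=0.4)], seed=7,
        )
        panel = gen_genotypes(cfg)
        grm = her.build_grm(her.filter_maf(panel, 0.01))
        y = phen["t"].to_numpy()
        d, U = grm.eigendecomposition()
        yt, Xt = U.T @ y, U.T @ np.ones((len(y), 1))
        vg = ve = y.var(ddof=1) / 2
        logl, w, beta, r, XtVX = her._reml_pieces(d, yt, Xt, vg, ve)
        prev = -np.inf
        for _ in range(25):
            assert logl >= prev - 1e-9
            prev = logl
            py = her._apply_p(yt, w, Xt, XtVX)
            papy = her._apply_p(d * py, w, Xt, XtVX)
            ppy = her._apply_p(py, w, Xt, XtVX)
            n = len(y)
            vg += vg * vg * (float(yt @ papy) - her._trace_pa(d, w, Xt, XtVX)) / n
            ve += ve * ve * (
                float(yt @ ppy) - her._trace_pa(np.ones(n), w, Xt, XtVX)
            ) / n
            logl, w, beta, r, XtVX = her._reml_pieces(d, yt, Xt, vg, ve)

    def test_phenotype_variance_required(self):
        grm = her.build_grm(
            her.filter_maf(gen_genotypes(PanelSimConfig(n_lines=20, n_snps=50, seed=1)), 0.01)
        )
        with pytest.raises(DegenerateInputError):
            her.greml_fit(grm, np.ones(20))


class TestSnpSubset:
    def test_full_subset_reproduces_genome_wide_fit(self, small_panel):
        panel, phen = small_panel
        panel = her.filter_maf(panel, 0.01)
        full = her.greml_fit(her.build_grm(panel), phen["t0"])
        sub = her.greml_on_snp_subset(panel, list(panel.snp_ids), phen["t0"])
        assert sub == full  # dataclass equality: bit-for-bit identical fields

    def test_causal_subset_captures_at_least_genome_wide_signal(self):
        causal = np.arange(50)
        cfg = PanelSimConfig(
            n_lines=600, n_snps=2000,
            traits=[TraitArchitecture("t", causal, h2=0.5)], seed=9,
        )
        panel = gen_genotypes(cfg)
        phen = gen_phenotypes(panel, cfg)
        fpanel = her.filter_maf(panel, 0.01)
        full = her.greml_fit(her.build_grm(fpanel), phen["t"])
        causal_ids = [panel.snp_ids[i] for i in causal]
        causal_ids = [s for s in causal_ids if s in set(fpanel.snp_ids)]
        sub = her.greml_on_snp_subset(fpanel, causal_ids, phen["t"])
        assert sub.heritability >= full.heritability - 0.1
        assert sub.n_snps == len(causal_ids)

    def test_single_snp_variance_share(self):
        # a rank-1 GRM leaves one degree of freedom for Vg, so single
        # fits are noisy; the mean over replicates recovers the 10% share
        ests = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            cfg = PanelSimConfig(n_lines=1000, n_snps=50, seed=seed)
            panel = gen_genotypes(cfg)
            g = panel.dosages[:, 0].copy()
            e = rng.normal(0.0, np.sqrt(g.var() * 9.0), panel.n_lines)
            res = her.greml_on_snp_subset(panel, [panel.snp_ids[0]], g + e)
            ests.append(res.heritability)
        assert 0.02 <= np.mean(ests) <= 0.2

    def test_unknown_snp_id_raises(self, small_panel):
        panel, phen = small_panel
        with pytest.raises(UnknownIdError):
            her.greml_on_snp_subset(panel, ["nope"], phen["t0"])


class TestScreen:
    def test_all_null_p_values_screened_out(self):
        r = her.GremlResult(1, 1, 0.5, 0.1, 0, 0, 0, 0.5, 100, 10, 5, True, False)
        assert her.screen_heritable_traits({"a": r, "b": r}) == []

    def test_boundary_alpha_excluded(self):
        r = her.GremlResult(1, 1, 0.5, 0.1, 0, 0, 0, 0.05, 100, 10, 5, True, False)
        assert her.screen_heritable_traits({"a": r}, alpha=0.05) == []

    def test_power_and_type_i_on_simulated_battery(self):
        causal = np.arange(40)
        traits = [TraitArchitecture(f"h{t}", causal, h2=0.5) for t in range(6)]
        traits += [TraitArchitecture(f"n{t}", causal, h2=0.0) for t in range(6)]
        cfg = PanelSimConfig(n_lines=500, n_snps=2000, traits=traits, seed=21)
        panel = gen_genotypes(cfg)
        phen = gen_phenotypes(panel, cfg)
        grm = her.build_grm(her.filter_maf(panel, 0.01))
        results = {t: her.greml_fit(grm, phen[t]) for t in phen.columns}
        retained = set(her.screen_heritable_traits(results))
        heritable = {f"h{t}" for t in range(6)}
        null = {f"n{t}" for t in range(6)}
        assert len(retained & heritable) >= 5
        assert len(retained & null) <= 1
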