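"""Meta-analysis statistics against closed forms and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hst

from behavarch import qtl_meta
from behavarch.errors import (
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
    UnknownIdError,
)


def make_records(pve_by_cat, **extra):
    rows = []
    for cat, values in pve_by_cat.items():
        for i, v in enumerate(values):
            rows.append(
                dict(
                    study_id=f"{cat}_{i // 3}",
                    species_a="sp1",
                    species_b="sp1",
                    taxon_class="insect",
                    behavioral_category=cat,
                    trait_name=f"{cat}_t{i}",
                    effect_size_pve=v,
                    lod=3.0,
                    neglog10_p=np.nan,
                    sample_size=100,
                    generations_diverged=1e5,
                    years_diverged=1e5,
                    cross_type="intraspecific",
                    **extra,
                )
            )
    return pd.DataFrame(rows)


class TestLodConversion:
    def test_zero_maps_to_zero(self):
        assert qtl_meta.lod_to_neglog10p(0.0) == 0.0

    def test_matches_chi_square_oracle(self):
        # LOD 3 <-> chi2 statistic 2 ln(10) * 3 = 13.8155 on 1 df
        expected = -math.log10(st.chi2.sf(2 * math.log(10) * 3.0, 1))
        assert qtl_meta.lod_to_neglog10p(3.0) == pytest.approx(expected, abs=1e-12)
        assert qtl_meta.lod_to_neglog10p(3.0) == pytest.approx(3.70, abs=0.01)

    def test_huge_lod_does_not_underflow(self):
        assert np.isfinite(qtl_meta.lod_to_neglog10p(5000.0))

    def test_negative_lod_rejected(self):
        with pytest.raises(ValueError):
            qtl_meta.lod_to_neglog10p(-1.0)

    @given(hst.lists(hst.floats(0.01, 50.0), min_size=2, max_size=10, unique=True))
    def test_strictly_increasing(self, lods):
        lods = sorted(lods)
        out = qtl_meta.lod_to_neglog10p(np.array(lods))
        assert (np.diff(out) > 0).all()


class TestSummaries:
    def test_single_record(self):
        df = make_records({"a": [10.0], "b": [5.0]})
        overall, per_cat = qtl_meta.summarize_by_category(df)
        assert overall.mean_pve == 7.5
        assert per_cat.loc["a", "mean_pve"] == 10.0
        assert per_cat.loc["a", "fraction_pve_below_20"] == 1.0

    def test_two_record_arithmetic(self):
        df = make_records({"a": [10.0, 30.0]})
        overall, _ = qtl_meta.summarize_by_category(df)
        assert overall.mean_pve == 20.0
        assert overall.fraction_pve_below_20 == 0.5  # strict < 20

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            qtl_meta.summarize_by_category(pd.DataFrame())


class TestRankTests:
    def test_identical_groups_give_null_result(self):
        df = make_records({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        stat, p = qtl_meta.category_vs_rest_test(df, "a")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self):
        df = make_records({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        stat, p = qtl_meta.category_vs_rest_test(df, "a", method="exact")
        # oracle: enumerate all C(6,3) group assignments with scipy's H
        pooled = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        h_obs = st.kruskal(pooled[:3], pooled[3:]).statistic
        count = total = 0
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            h = st.kruskal(pooled[list(comb)], pooled[rest]).statistic
            count += h >= h_obs - 1e-12
            total += 1
        assert p == pytest.approx(count / total)
        assert stat == pytest.approx(h_obs)

    def test_exact_agrees_with_oracle_under_ties(self):
        df = make_records({"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 4.0]})
        _, p = qtl_meta.category_vs_rest_test(df, "a", method="exact")
        pooled = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        h_obs = st.kruskal(pooled[:3], pooled[3:]).statistic
        count = total = 0
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            h = st.kruskal(pooled[list(comb)], pooled[rest]).statistic
            count += h >= h_obs - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_missing_category_raises(self):
        df = make_records({"a": [1.0], "b": [2.0]})
        with pytest.raises(UnknownIdError):
            qtl_meta.category_vs_rest_test(df, "zzz")

    def test_cross_type_requires_both_groups(self):
        df = make_records({"a": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            qtl_meta.cross_type_test(df)

    def test_cross_type_exact_matches_category_machinery(self):
        df = make_records({"a": [1.0, 2.0, 3.0]})
        inter = make_records({"a": [7.0, 8.0, 9.0]})
        inter["cross_type"] = "interspecific"
        inter["species_b"] = "sp2"
        df = pd.concat([df, inter], ignore_index=True)
        _, p_exact = qtl_meta.cross_type_test(df, method="exact")
        assert p_exact == pytest.approx(2 / 20)  # only the two extreme splits


class TestPermutationTest:
    def test_dominant_category_gives_p_zero(self):
        df = make_records({"a": [50.0, 60.0], "b": [1.0, 2.0, 3.0, 4.0]})
        res = qtl_meta.permutation_category_test(df, "a", n_perm=500, seed=0)
        assert res.p_value == 0.0

    def test_three_draw_enumeration_limit(self):
        # category {9} vs complement {1, 5, 13}: null means are the three
        # values, and exactly one exceeds 9 -> p converges to 1/3
        df = make_records({"a": [9.0], "b": [1.0, 5.0, 13.0]})
        res = qtl_meta.permutation_category_test(df, "a", n_perm=6000, seed=1)
        assert res.observed_mean == 9.0
        assert res.p_value == pytest.approx(1 / 3, abs=0.03)

    def test_deterministic_given_seed(self):
        df = make_records({"a": [9.0, 11.0], "b": list(np.linspace(1, 20, 12))})
        r1 = qtl_meta.permutation_category_test(df, "a", n_perm=300, seed=5)
        r2 = qtl_meta.permutation_category_test(df, "a", n_perm=300, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.null_mean == r2.null_mean

    def test_plus_one_correction(self):
        df = make_records({"a": [50.0], "b": [1.0, 2.0]})
        res = qtl_meta.permutation_category_test(df, "a", n_perm=100, seed=0,
                                                 plus_one=True)
        assert res.p_value == pytest.approx(1 / 101)

    def test_small_complement_rejected(self):
        df = make_records({"a": [1.0, 2.0, 3.0], "b": [4.0]})
        with pytest.raises(InsufficientDataError):
            qtl_meta.permutation_category_test(df, "a")


class TestDivergenceCorrelation:
    def test_perfect_linear_relation(self):
        df = make_records({"a": [1.0] * 4})
        df["years_diverged"] = [1e4, 1e5, 1e6, 1e7]
        df["effect_size_pve"] = [2.0, 4.0, 6.0, 8.0]  # linear in log10(years)
        r, r2, p = qtl_meta.divergence_effect_correlation(df)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        df = make_records({"a": [1.0] * 4})
        df["years_diverged"] = [1e4, 1e5, 1e6, 1e7]
        df["effect_size_pve"] = [3.0, 1.0, 4.0, 1.5]
        x = np.log10(df["years_diverged"].to_numpy())
        y = df["effect_size_pve"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        r, r2, _ = qtl_meta.divergence_effect_correlation(df)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert r2 == pytest.approx(r_hand**2, abs=1e-12)

    def test_zero_variance_rejected(self):
        df = make_records({"a": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateInputError):
            qtl_meta.divergence_effect_correlation(df)


class TestLmm:
    def test_no_random_effects_reduces_to_ols(self, qtl_table):
        fit = qtl_meta.fit_lmm_effects(qtl_table, random_structure=())
        # independent OLS via normal equations on the same design
        cats = sorted(qtl_table["behavioral_category"].unique())
        X = np.ones((len(qtl_table), len(cats)))
        for j, c in enumerate(cats[1:], start=1):
            X[:, j] = (qtl_table["behavioral_category"] == c).astype(float)
        y = qtl_table["effect_size_pve"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.fixed_effects["estimate"].to_numpy(),
                                   beta, atol=1e-8)

    def test_recovers_simulated_category_shift(self):
        rng = np.random.default_rng(8)
        n = 250
        base = rng.exponential(8.0, n)
        df = make_records({"a": list(base), "b": list(base + 10.0)})
        df["study_id"] = [f"s{i % 25}" for i in range(len(df))]
        df["sample_size"] = rng.integers(50, 400, len(df))
        df["generations_diverged"] = 10 ** rng.uniform(4, 8, len(df))
        fit = qtl_meta.fit_lmm_effects(df)
        row = fit.fixed_effects.loc["C(behavioral_category)[T.b]"]
        assert abs(row["estimate"] - 10.0) <= 2 * row["se"]
        assert fit.converged

    def test_single_category_rejected(self):
        df = make_records({"a": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            qtl_meta.fit_lmm_effects(df)
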