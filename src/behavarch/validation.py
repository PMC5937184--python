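"""Simulation studies validating the estimators end to end.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage(s), and returns summary numbers: closed-form oracle
deviations, GREML recovery bias, permutation-test calibration, and
directionality power/specificity.  They are used by the acceptance
checks and are handy for re-validating after any numerical change.

Problem sizes are chosen to finish in minutes on one core while keeping
each estimate's Monte-Carlo error well inside the tolerance it is
compared against (see docs/methods.md).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats as st

from . import directionality as dr
from . import gwas
from . import heritability as her
from . import qtl_meta
from .errors import ScreenedOutError
from .simulate import (
    PanelSimConfig,
    QtlSimConfig,
    TraitArchitecture,
    chain_pair_config,
    fork_pair_config,
    gen_genotypes,
    gen_phenotypes,
    gen_qtl_table,
)

#: hit threshold used in the desk-scale pair simulations (O(10^3) SNP
#: panels; ~0.15 expected false hits per scan)
PANEL_SCALE_P_THRESHOLD = 1e-4


# ---------------------------------------------------------------------------
# closed-form / enumeration oracles
# ---------------------------------------------------------------------------

def assoc_scan_oracle_error(seed: int, n_lines: int = 120, n_snps: int = 60) -> float:
    """Max |deviation| of scan beta/SE from per-SNP scipy.stats.linregress."""
    cfg = PanelSimConfig(n_lines=n_lines, n_snps=n_snps, inbred=False,
                         seed=seed)
    panel = gen_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(rng.standard_normal(n_lines), index=panel.line_ids)
    res = gwas.assoc_scan(panel, y)
    worst = 0.0
    for j, sid in enumerate(panel.snp_ids):
        if not res.table.loc[sid, "testable"]:
            continue
        lr = st.linregress(panel.dosages[:, j], y.to_numpy())
        worst = max(
            worst,
            abs(res.table.loc[sid, "BETA"] - lr.slope),
            abs(res.table.loc[sid, "SE"] - lr.stderr),
        )
    return worst


def rank_test_oracle_error(seed: int) -> float:
    """Max |p difference| between the exact rank test and full enumeration.

    The oracle enumerates every assignment of the pooled values to the
    two group sizes and scores scipy's Kruskal-Wallis statistic.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n1, n2 in [(3, 3), (2, 4), (3, 2)]:
        values = np.round(rng.normal(10, 4, n1 + n2), 1)
        df = pd.DataFrame(
            dict(
                behavioral_category=["a"] * n1 + ["b"] * n2,
                effect_size_pve=values,
            )
        )
        _, p = qtl_meta.category_vs_rest_test(df, "a", method="exact")
        h_obs = st.kruskal(values[:n1], values[n1:]).statistic
        count = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            rest = [i for i in range(n1 + n2) if i not in comb]
            h = st.kruskal(values[list(comb)], values[rest]).statistic
            count += h >= h_obs - 1e-12
            total += 1
        worst = max(worst, abs(p - count / total))
    return worst


def grm_oracle_error() -> float:
    """Max |deviation| of the GRM from its hand-computed 3x2 toy value."""
    from .panel import GenotypePanel

    snps = pd.DataFrame(
        {"chrom": ["1", "1"], "pos": [1, 2], "a1": ["A", "A"], "a2": ["T", "T"]},
        index=pd.Index(["s1", "s2"], name="snp_id"),
    )
    panel = GenotypePanel(
        line_ids=["l1", "l2", "l3"],
        snps=snps,
        dosages=np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]]),
        inbred=False,
    )
    expected = np.array(
        [[2.5, -2.0, -0.5], [-2.0, 2.5, -0.5], [-0.5, -0.5, 1.0]]
    )
    return float(np.abs(her.build_grm(panel).matrix - expected).max())


# ---------------------------------------------------------------------------
# GREML recovery
# ---------------------------------------------------------------------------

def greml_recovery_study(
    seed: int,
    n_reps: int = 50,
    n_lines: int = 1000,
    n_snps: int = 5000,
    h2_levels: tuple[float, ...] = (0.0, 0.2, 0.5, 0.8),
    n_causal: int = 100,
) -> pd.DataFrame:
    """Mean bias of the GREML heritability over seeded replicates.

    Each replicate draws one genotype panel, builds (and factorizes) one
    genome-wide GRM, and fits every h2 level on its own phenotype draw.
    Returns a DataFrame indexed by h2 with columns ``mean_bias``,
    ``mean_abs_error`` and ``n_reps``.
    """
    errors: dict[float, list[float]] = {h2: [] for h2 in h2_levels}
    for rep in range(n_reps):
        base = seed + 1000 * rep
        traits = [
            TraitArchitecture(f"h{int(100 * h2)}",
                              np.arange(n_causal) * (n_snps // n_causal), h2=h2)
            for h2 in h2_levels
        ]
        cfg = PanelSimConfig(n_lines=n_lines, n_snps=n_snps, traits=traits,
                             seed=base)
        panel = gen_genotypes(cfg)
        phen = gen_phenotypes(panel, cfg)
        grm = her.build_grm(her.filter_maf(panel, 0.01))
        for h2, trait in zip(h2_levels, traits):
            fit = her.greml_fit(grm, phen[trait.name])
            errors[h2].append(fit.heritability - h2)
    rows = {
        h2: dict(
            mean_bias=float(np.mean(errs)),
            mean_abs_error=float(np.mean(np.abs(errs))),
            n_reps=n_reps,
        )
        for h2, errs in errors.items()
    }
    return pd.DataFrame(rows).T.rename_axis("h2")


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def permutation_category_calibration(
    seed: int, n_datasets: int = 500, n_cat: int = 124, n_rest: int = 883,
    n_perm: int = 500,
) -> float:
    """KS P-value of permutation-test P-values under random category labels.

    Group sizes default to the compiled-table regime the test is used in
    (a ~12% category against the rest).  Because the null resamples the
    *complement*, whose mean anticorrelates with the category mean, the
    literal procedure is only asymptotically calibrated as the category
    fraction shrinks; at these proportions the type-I error is nominal.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        values = rng.exponential(10.0, n_cat + n_rest)
        df = pd.DataFrame(
            dict(
                behavioral_category=["a"] * n_cat + ["b"] * n_rest,
                effect_size_pve=values,
            )
        )
        res = qtl_meta.permutation_category_test(
            df, "a", n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals[i] = res.p_value
    return float(st.kstest(pvals, "uniform").pvalue)


def directionality_null_calibration(
    seed: int, n_datasets: int = 500, length: int = 20, n_perm: int = 200
) -> float:
    """KS P-value of the D permutation test under fully null vectors."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        xx, xy = rng.standard_normal((2, length))
        yy, yx = rng.standard_normal((2, length))
        _, pvals[i] = dr.permutation_p(
            xx, xy, yy, yx, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    return float(st.kstest(pvals, "uniform").pvalue)


def gwas_null_calibration(seed: int, n_lines: int = 200, n_snps: int = 20_000) -> float:
    """KS P-value of scan P-values for a phenotype permuted across lines."""
    cfg = PanelSimConfig(n_lines=n_lines, n_snps=n_snps, seed=seed)
    panel = gen_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(rng.permutation(rng.standard_normal(n_lines)),
                  index=panel.line_ids)
    res = gwas.assoc_scan(panel, y)
    p = res.table.loc[res.table["testable"], "P"]
    return float(st.kstest(p, "uniform").pvalue)


# ---------------------------------------------------------------------------
# directionality power / specificity
# ---------------------------------------------------------------------------

def _pair_p(config, seed: int, threshold: float) -> float | None:
    panel = gen_genotypes(config)
    phen = gen_phenotypes(panel, config)
    scans = {t: gwas.assoc_scan(panel, phen[t], trait=t) for t in phen.columns}
    hits = {t: gwas.significant_hits(s, threshold) for t, s in scans.items()}
    em = gwas.build_effect_matrix(scans, hits)
    try:
        result = dr.test_trait_pair(em, "p1", "p2", n_perm=1000, seed=seed + 1)
    except ScreenedOutError:
        return None
    return result.p_perm


def directionality_power_study(
    seed: int, n_chain: int = 25, n_fork: int = 200,
    threshold: float = PANEL_SCALE_P_THRESHOLD,
) -> dict:
    """Detection rate on mediated pairs; false-positive rate on forks.

    Chain pairs use the generator's stated strong-effect conditions; a
    replicate counts as detected when the permutation P falls below 0.05.
    Screened-out replicates (too few hits) count as not detected.
    """
    chain_p = [
        _pair_p(chain_pair_config(seed=seed + 7 * i), seed + 7 * i, threshold)
        for i in range(n_chain)
    ]
    fork_p = [
        _pair_p(fork_pair_config(seed=seed + 13 * i + 3), seed + 13 * i + 3,
                threshold)
        for i in range(n_fork)
    ]
    chain_detected = sum(1 for p in chain_p if p is not None and p < 0.05)
    fork_rejections = sum(1 for p in fork_p if p is not None and p < 0.05)
    fork_tested = sum(1 for p in fork_p if p is not None)
    return dict(
        chain_power=chain_detected / n_chain,
        n_chain=n_chain,
        fork_fpr=fork_rejections / max(fork_tested, 1),
        n_fork_tested=fork_tested,
    )


# ---------------------------------------------------------------------------
# synthetic meta-analysis run
# ---------------------------------------------------------------------------

def meta_analysis_run(seed: int, n_perm: int = 10_000) -> dict:
    """Full meta-analysis of the default synthetic compiled-QTL table."""
    table = gen_qtl_table(QtlSimConfig(seed=seed))
    overall, per_cat = qtl_meta.summarize_by_category(table)
    kw_stat, kw_p = qtl_meta.category_vs_rest_test(table, "courtship")
    perm = qtl_meta.permutation_category_test(
        table, "courtship", n_perm=n_perm, seed=seed + 1
    )
    r, r2, p_div = qtl_meta.divergence_effect_correlation(table)
    _, p_cross = qtl_meta.cross_type_test(table)
    lmm = qtl_meta.fit_lmm_effects(table)
    courtship = lmm.fixed_effects.loc["C(behavioral_category)[T.courtship]"]
    return dict(
        n_loci=int(len(table)),
        mean_pve=overall.mean_pve,
        fraction_pve_below_20=overall.fraction_pve_below_20,
        courtship_mean_ratio=(
            per_cat.loc["courtship", "mean_pve"]
            / table.loc[
                table["behavioral_category"] != "courtship", "effect_size_pve"
            ].mean()
        ),
        courtship_kw_p=kw_p,
        courtship_perm_p=perm.p_value,
        divergence_r2=r2,
        cross_type_p=p_cross,
        lmm_courtship_estimate=float(courtship["estimate"]),
        lmm_courtship_se=float(courtship["se"]),
        lmm_converged=bool(lmm.converged),
    )
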