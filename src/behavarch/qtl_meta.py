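"""Comparative meta-analysis of QTL effect sizes across behavioral categories.

Operates on a compiled QTL table (one row per significant locus; see
:mod:`behavarch.io` for the schema).  The effect-size unit throughout is
PVE — the percent of phenotypic variance explained by the locus in its
mapping population.

Provides: LOD -> -log10(P) conversion, per-category summaries, two-group
rank tests of one category against the rest, a permutation null for
category means built by resampling the complementary effect sizes without
replacement, the divergence/effect-size correlation, and linear
mixed-effects models of PVE on category with study-level random effects
(REML here; the Gibbs-sampled Bayesian version lives in
:mod:`behavarch.bayes`).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
    UnknownIdError,
)

_LN10 = math.log(10.0)

#: random-effect terms understood by the mixed models (see ``_build_z``)
RANDOM_EFFECT_TERMS = ("sample_size", "generations", "cross_type")


def lod_to_neglog10p(lod):
    """Convert linkage LOD scores to -log10 P-values.

    Uses the likelihood-ratio equivalence of interval mapping: a LOD of L
    corresponds to a chi-square statistic 2*ln(10)*L on 1 df, and the
    P-value is that chi-square's upper-tail probability.  Computed on the
    log scale so very large LODs do not underflow.

    Accepts scalars or arrays; strictly increasing in LOD and 0 at LOD 0.
    """
    arr = np.asarray(lod, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("LOD scores must be nonnegative")
    # for a 1-df chi-square, sf(x) = 2 * Phi(-sqrt(x)); the normal logsf
    # stays accurate far into the tail where chi2.sf underflows
    stat = 2.0 * _LN10 * arr
    out = -(math.log(2.0) + st.norm.logsf(np.sqrt(stat))) / _LN10
    out = np.where(stat == 0.0, 0.0, out)
    if np.isscalar(lod):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# summaries and rank tests
# ---------------------------------------------------------------------------

@dataclass
class CategorySummary:
    category: str
    n_loci: int
    mean_pve: float
    median_pve: float
    fraction_pve_below_20: float


def summarize_by_category(records: pd.DataFrame) -> tuple[CategorySummary, pd.DataFrame]:
    """Global and per-category effect-size summaries.

    Returns ``(global_summary, per_category)`` where the global summary
    covers all loci (category label ``"all"``) and ``per_category`` is a
    DataFrame indexed by category with columns ``n_loci``, ``mean_pve``,
    ``median_pve`` and ``fraction_pve_below_20`` (strict ``< 20``).
    """
    if records is None or len(records) == 0:
        raise EmptyInputError("no QTL records to summarize")
    pve = records["effect_size_pve"].astype(float)
    overall = CategorySummary(
        category="all",
        n_loci=len(pve),
        mean_pve=float(pve.mean()),
        median_pve=float(pve.median()),
        fraction_pve_below_20=float((pve < 20.0).mean()),
    )
    grouped = records.groupby("behavioral_category")["effect_size_pve"]
    per_cat = pd.DataFrame(
        {
            "n_loci": grouped.size(),
            "mean_pve": grouped.mean(),
            "median_pve": grouped.median(),
            "fraction_pve_below_20": grouped.apply(lambda s: float((s < 20.0).mean())),
        }
    )
    return overall, per_cat


def _two_group_values(records: pd.DataFrame, category: str):
    mask = records["behavioral_category"] == category
    if not mask.any():
        raise UnknownIdError(f"category {category!r} not present")
    x = records.loc[mask, "effect_size_pve"].to_numpy(dtype=float)
    y = records.loc[~mask, "effect_size_pve"].to_numpy(dtype=float)
    if y.size == 0:
        raise InsufficientDataError("complement of the category is empty")
    return x, y


def _kruskal_two_groups(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 0.0, 1.0  # all observations tied: no rank information
    stat, p = st.kruskal(x, y)
    return float(stat), float(p)


def _kruskal_statistic(values: np.ndarray, n1: int) -> float:
    """Tie-corrected Kruskal-Wallis H for the split (first n1 | rest)."""
    n = values.size
    ranks = st.rankdata(values)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / (n - n1)) - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def category_vs_rest_test(
    records: pd.DataFrame, category: str, method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-group rank test of one category's PVE against all other loci.

    A Kruskal-Wallis test on two groups (equivalent to a tie-corrected
    Wilcoxon rank-sum) asking whether loci of the focal behavioral
    category explain more/less phenotypic variance than the remaining
    loci.  ``method="exact"`` enumerates every assignment of the pooled
    values to the two group sizes (feasible only for small tables) and
    returns the exact permutation P of the H statistic.

    Returns ``(statistic, p_value)``.
    """
    x, y = _two_group_values(records, category)
    if method == "asymptotic":
        return _kruskal_two_groups(x, y)
    if method != "exact":
        raise ValueError("method must be 'asymptotic' or 'exact'")
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    if math.comb(n, n1) > 200_000:
        raise InsufficientDataError(
            "exact enumeration infeasible for these group sizes"
        )
    h_obs = _kruskal_statistic(pooled, n1)
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n1):
        rest = np.setdiff1d(idx, comb, assume_unique=True)
        h = _kruskal_statistic(np.concatenate([pooled[list(comb)], pooled[rest]]), n1)
        count += h >= h_obs - 1e-12
        total += 1
    return float(h_obs), count / total


def cross_type_test(records: pd.DataFrame, method: str = "asymptotic") -> tuple[float, float]:
    """Rank test of PVE between interspecific and intraspecific crosses."""
    inter = records.loc[
        records["cross_type"] == "interspecific", "effect_size_pve"
    ].to_numpy(dtype=float)
    intra = records.loc[
        records["cross_type"] == "intraspecific", "effect_size_pve"
    ].to_numpy(dtype=float)
    if inter.size == 0 or intra.size == 0:
        raise InsufficientDataError("both cross types must be present")
    if method == "exact":
        sub = records.copy()
        sub["behavioral_category"] = np.where(
            sub["cross_type"] == "interspecific", "inter", "intra"
        )
        return category_vs_rest_test(sub, "inter", method="exact")
    return _kruskal_two_groups(inter, intra)


# ---------------------------------------------------------------------------
# permutation null for category means
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    category: str
    observed_mean: float
    n_permutations: int
    p_value: float
    null_mean: float
    null_quantiles: dict[str, float] = field(default_factory=dict)


def permutation_category_test(
    records: pd.DataFrame,
    category: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test of a category's mean PVE against resampled nulls.

    The null distribution is built by drawing, ``n_perm`` times, as many
    effect sizes as the category contains from the *complementary* loci
    without replacement, and recording each draw's mean.  The P-value is
    the fraction of null means strictly greater than the observed category
    mean; ``plus_one=True`` switches to the small-sample-safe
    ``(count + 1) / (n_perm + 1)`` variant.
    """
    x, y = _two_group_values(records, category)
    n_cat = x.size
    if y.size < n_cat:
        raise InsufficientDataError(
            f"complement ({y.size}) smaller than category ({n_cat})"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(x.mean())
    # vectorized draws without replacement: the first n_cat positions of a
    # random permutation of the complement, one permutation per row
    order = np.argsort(rng.random((n_perm, y.size)), axis=1)[:, :n_cat]
    null_means = y[order].mean(axis=1)
    count = int((null_means > observed).sum())
    p = (count + 1) / (n_perm + 1) if plus_one else count / n_perm
    qs = np.quantile(null_means, [0.025, 0.5, 0.975])
    return PermutationResult(
        category=category,
        observed_mean=observed,
        n_permutations=n_perm,
        p_value=float(p),
        null_mean=float(null_means.mean()),
        null_quantiles={"q025": float(qs[0]), "q50": float(qs[1]), "q975": float(qs[2])},
    )


# ---------------------------------------------------------------------------
# divergence correlation
# ---------------------------------------------------------------------------

def divergence_effect_correlation(records: pd.DataFrame) -> tuple[float, float, float]:
    """Pearson correlation of log10(years diverged) with effect size.

    Returns ``(r, r_squared, p_value)``.  Requires strictly positive
    divergence times; raises on zero variance in either variable.
    """
    years = records["years_diverged"].to_numpy(dtype=float)
    pve = records["effect_size_pve"].to_numpy(dtype=float)
    keep = np.isfinite(years) & np.isfinite(pve)
    years, pve = years[keep], pve[keep]
    if years.size < 3:
        raise InsufficientDataError("need >= 3 records with divergence data")
    if np.any(years <= 0):
        raise DegenerateInputError("years_diverged must be > 0 for all records")
    x = np.log10(years)
    if np.ptp(x) == 0 or np.ptp(pve) == 0:
        raise DegenerateInputError("zero variance in divergence or effect size")
    res = st.pearsonr(x, pve)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


# ---------------------------------------------------------------------------
# frequentist linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, p
    random_variances: dict[str, float]
    residual_variance: float
    converged: bool
    singular: bool
    log_likelihood: float
    reference_category: str


def _prepare_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Centred/scaled covariates used by both mixed-model fits.

    Sample size and generations are z-scored (generations on the log10
    scale, since divergences span orders of magnitude) so the random-slope
    variances are comparable and the samplers are well conditioned.
    """
    df = records.copy()
    n = df["sample_size"].astype(float)
    g = np.log10(df["generations_diverged"].astype(float).clip(lower=1.0))
    df["sample_size_z"] = (n - n.mean()) / (n.std(ddof=0) or 1.0)
    df["generations_z"] = (g - g.mean()) / (g.std(ddof=0) or 1.0)
    return df


def fit_lmm_effects(
    records: pd.DataFrame,
    random_structure: tuple[str, ...] = ("sample_size", "generations"),
) -> LmmFit:
    """REML linear mixed model of PVE on behavioral category.

    Fixed effect: behavioral category (treatment-coded against the
    alphabetically first category).  Random effects: a study intercept
    plus, per requested term, an independent random slope of the centred,
    scaled covariate grouped by study (``sample_size``, ``generations``)
    or a random intercept per cross type (``cross_type``).  With an empty
    ``random_structure`` the model reduces to ordinary least squares.

    Non-convergence and singular fits are flagged on the result, never
    silently dropped.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if records["behavioral_category"].nunique() < 2:
        raise InsufficientDataError("need >= 2 behavioral categories")
    df = _prepare_covariates(records)
    ref = sorted(df["behavioral_category"].unique())[0]

    if not random_structure:
        res = smf.ols("effect_size_pve ~ C(behavioral_category)", data=df).fit()
        fe = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "p": res.pvalues}
        )
        return LmmFit(
            fixed_effects=fe,
            random_variances={},
            residual_variance=float(res.mse_resid),
            converged=True,
            singular=False,
            log_likelihood=float(res.llf),
            reference_category=ref,
        )

    vc = {}
    for term in random_structure:
        if term == "sample_size":
            vc["sample_size"] = "0 + sample_size_z"
        elif term == "generations":
            vc["generations"] = "0 + generations_z"
        elif term == "cross_type":
            vc["cross_type"] = "0 + C(cross_type)"
        else:
            raise ValueError(f"unknown random-effect term {term!r}")

    model = smf.mixedlm(
        "effect_size_pve ~ C(behavioral_category)",
        data=df,
        groups=df["study_id"],
        re_formula="1",
        vc_formula=vc,
    )
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
                singular = True
    fe_names = [n for n in res.params.index if not n.endswith("Var") and n != "Group Var"]
    fe = pd.DataFrame(
        {
            "estimate": res.params[fe_names],
            "se": res.bse[fe_names],
            "p": res.pvalues[fe_names],
        }
    )
    rv = {"study_intercept": float(res.cov_re.iloc[0, 0])} if res.cov_re.size else {}
    for name, val in zip(vc, np.atleast_1d(res.vcomp)):
        rv[name] = float(val)
    return LmmFit(
        fixed_effects=fe,
        random_variances=rv,
        residual_variance=float(res.scale),
        converged=bool(res.converged),
        singular=singular,
        log_likelihood=float(res.llf),
        reference_category=ref,
    )
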