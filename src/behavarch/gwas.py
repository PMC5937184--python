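"""Single-SNP association scans and cross-trait pleiotropy summaries.

The association model is deliberately simple — per SNP, ordinary least
squares of the line-mean phenotype on allele dosage with an intercept,
two-sided t test on n-2 df — matching the basic quantitative association
test of standard GWAS toolkits on inbred-line panels.  Downstream, hit
sets at a nominal threshold are combined into (i) a binary SNP x trait
pleiotropy incidence restricted to SNPs significant for at least two
traits, and (ii) a dense significant-SNP x trait matrix of effect sizes
whose Spearman correlation structure summarizes shared genetic effects
between traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import EmptyInputError, InsufficientDataError
from .panel import GenotypePanel

#: nominal genome-wide threshold used for behavioral trait scans
DEFAULT_P_THRESHOLD = 5e-6
#: the more lenient threshold used when intersecting with a second battery
RELAXED_P_THRESHOLD = 1e-5


@dataclass
class AssocResult:
    """Per-SNP simple-regression association results for one trait.

    ``table`` columns follow the qassoc layout: SNP, CHR, BP, NMISS,
    BETA, SE, STAT (t), P, plus a boolean ``testable`` flag for SNPs
    with nonzero dosage variance among phenotyped lines.
    """

    trait: str
    table: pd.DataFrame
    n_lines: int

    @property
    def p_values(self) -> pd.Series:
        return self.table["P"]


def assoc_scan(panel: GenotypePanel, phenotype: pd.Series, trait: str | None = None) -> AssocResult:
    """Regression of a per-line phenotype on dosage, one SNP at a time.

    ``phenotype`` is indexed by line id; lines missing from the panel or
    with missing values are dropped; per SNP, lines with missing dosage
    are additionally dropped.  Monomorphic SNPs (zero dosage variance
    among the used lines) are marked ``testable=False`` with NaN
    statistics rather than aborting the scan.
    """
    trait = trait or getattr(phenotype, "name", None) or "trait"
    y_full = phenotype.reindex(panel.line_ids)
    keep = y_full.notna().to_numpy()
    if keep.sum() < 3:
        raise InsufficientDataError("need >= 3 lines with non-missing phenotype")
    y = y_full.to_numpy(dtype=float)[keep]
    X = panel.dosages[keep, :]

    finite = np.isfinite(X)
    n = finite.sum(axis=0).astype(float)
    Xz = np.where(finite, X, 0.0)
    yv = y[:, None]
    sum_x = Xz.sum(axis=0)
    sum_y = (finite * yv).sum(axis=0)
    sum_xx = (Xz * Xz).sum(axis=0)
    sum_xy = (Xz * yv).sum(axis=0)
    sum_yy = (finite * yv * yv).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = sum_xx - sum_x * sum_x / n
        sxy = sum_xy - sum_x * sum_y / n
        syy = sum_yy - sum_y * sum_y / n
        beta = sxy / sxx
        rss = syy - beta * sxy
        dfree = n - 2
        sigma2 = rss / dfree
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    testable = np.isfinite(sxx) & (sxx > 1e-12) & (dfree > 0)
    with np.errstate(invalid="ignore"):
        p = 2.0 * st.t.sf(np.abs(tstat), dfree)
    beta = np.where(testable, beta, np.nan)
    se = np.where(testable, se, np.nan)
    tstat = np.where(testable, tstat, np.nan)
    p = np.where(testable, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)

    table = pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "CHR": panel.snps["chrom"].to_numpy(),
            "BP": panel.snps["pos"].to_numpy(),
            "NMISS": n.astype(int),
            "BETA": beta,
            "SE": se,
            "STAT": tstat,
            "P": p,
            "testable": testable,
        }
    ).set_index("SNP")
    return AssocResult(trait=trait, table=table, n_lines=int(keep.sum()))


def significant_hits(result: AssocResult, threshold: float = DEFAULT_P_THRESHOLD) -> set[str]:
    """SNP ids with association P strictly below the threshold."""
    p = result.table["P"]
    return set(p.index[(p < threshold).fillna(False)])


@dataclass
class PleiotropyMatrix:
    """Binary incidence of significance for SNPs hitting >= 2 traits."""

    incidence: pd.DataFrame  # SNPs x traits, entries in {0, 1}
    snp_trait_counts: pd.Series
    gene_multitrait_counts: pd.Series | None = None
    unmatched_annotation_ids: list[str] = field(default_factory=list)


def build_pleiotropy_matrix(
    hit_sets: dict[str, set[str]],
    annotation: dict[str, str] | None = None,
) -> PleiotropyMatrix:
    """Cross-trait significance incidence restricted to multi-trait SNPs.

    ``hit_sets`` maps trait -> significant SNP ids.  The returned
    incidence keeps only SNPs significant for at least two traits.  With
    an annotation map (SNP id -> gene id) the per-gene count of
    multi-trait SNPs is reported for genes carrying >= 2 of them.
    """
    if len(hit_sets) < 2:
        raise InsufficientDataError("need >= 2 traits to assess pleiotropy")
    traits = list(hit_sets)
    all_snps = sorted(set().union(*hit_sets.values()))
    inc = pd.DataFrame(0, index=pd.Index(all_snps, name="SNP"), columns=traits, dtype=int)
    for t in traits:
        inc.loc[sorted(hit_sets[t]), t] = 1
    counts = inc.sum(axis=1)
    multi = counts >= 2
    inc = inc.loc[multi]
    counts = counts.loc[multi]

    gene_counts = None
    unmatched: list[str] = []
    if annotation is not None:
        known = set(all_snps)
        unmatched = sorted(s for s in annotation if s not in known)
        genes = pd.Series(
            {s: annotation[s] for s in inc.index if s in annotation}, name="gene"
        )
        if len(genes):
            gc = genes.groupby(genes).size()
            gene_counts = gc[gc >= 2]
        else:
            gene_counts = pd.Series(dtype=int)
    return PleiotropyMatrix(
        incidence=inc,
        snp_trait_counts=counts,
        gene_multitrait_counts=gene_counts,
        unmatched_annotation_ids=unmatched,
    )


@dataclass
class EffectMatrix:
    """Significant-SNP x trait matrix of association effect sizes.

    Rows are the union of the traits' hit sets; entry (s, t) is SNP s's
    regression beta in trait t's scan whether or not s is significant for
    t (NaN only where s was untestable in t).  ``hits`` records which
    SNPs were significant for which trait.
    """

    betas: pd.DataFrame
    hits: dict[str, set[str]]

    @property
    def traits(self) -> list[str]:
        return list(self.betas.columns)


def build_effect_matrix(
    scans: dict[str, AssocResult], hit_sets: dict[str, set[str]]
) -> EffectMatrix:
    """Assemble the effect-size matrix over the union of significant SNPs."""
    missing = [t for t in hit_sets if t not in scans]
    if missing:
        raise EmptyInputError(f"traits without a completed scan: {missing!r}")
    union = sorted(set().union(*hit_sets.values())) if hit_sets else []
    cols = {}
    for t, scan in scans.items():
        cols[t] = scan.table["BETA"].reindex(union)
    betas = pd.DataFrame(cols, index=pd.Index(union, name="SNP"))
    return EffectMatrix(betas=betas, hits={t: set(s) for t, s in hit_sets.items()})


def trait_correlation_structure(matrix: EffectMatrix, min_rows: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation of effect sizes between traits.

    Pairwise-complete over the rows of the effect matrix; a pair with
    fewer than ``min_rows`` complete rows is left NaN.  Symmetric with a
    unit diagonal.
    """
    if matrix.betas.shape[1] < 2:
        raise InsufficientDataError("need >= 2 traits")
    corr = matrix.betas.corr(method="spearman", min_periods=min_rows)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class SampleSizePvalueResult:
    rho: float
    p_value: float
    n_pairs: int
    defined: bool


def samplesize_pvalue_correlation(
    scans: dict[str, AssocResult],
    hit_sets: dict[str, set[str]],
) -> SampleSizePvalueResult:
    """Spearman correlation between per-SNP sample size and association P.

    Pools every (trait, significant SNP) pair; a diagnostic for sample-
    size-driven effect inflation across a trait battery.  Undefined (and
    flagged) when all pooled sample sizes are equal.
    """
    ns, ps = [], []
    for t, snps in hit_sets.items():
        sub = scans[t].table.loc[sorted(snps)]
        ns.append(sub["NMISS"].to_numpy(dtype=float))
        ps.append(sub["P"].to_numpy(dtype=float))
    if not ns or sum(len(a) for a in ns) < 3:
        raise InsufficientDataError("too few significant SNPs pooled")
    n_arr = np.concatenate(ns)
    p_arr = np.concatenate(ps)
    if np.ptp(n_arr) == 0:
        return SampleSizePvalueResult(float("nan"), float("nan"), len(n_arr), False)
    rho, p = st.spearmanr(n_arr, p_arr)
    return SampleSizePvalueResult(float(rho), float(p), len(n_arr), True)
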