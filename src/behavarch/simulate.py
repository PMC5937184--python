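"""Synthetic data generators for the meta-analysis and panel analyses.

Two generator families:

* :func:`gen_qtl_table` emulates a compiled behavioral-QTL meta-table —
  one row per significant locus with its effect size (% phenotypic variance
  explained, PVE), significance score, behavioral category, cross metadata,
  and evolutionary divergence of the cross parents.  Effect sizes follow an
  exponential distribution with category-specific means (many small loci,
  few large ones), truncated to (0, 100].

* :func:`gen_genotypes` / :func:`gen_phenotypes` emulate an inbred-line
  mapping panel: biallelic SNP dosages for fully inbred lines and additive
  per-line trait values with a controlled heritability, including "fork"
  (one genotype influencing two traits independently) and "chain" (genotype
  -> trait 1 -> trait 2) pleiotropy patterns for the directionality test.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
the seed is recorded in the output metadata so every table is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import GenotypePanel

# Default category composition of a compiled behavioral-QTL table:
# 1007 loci in 10 categories, with courtship loci carrying a mean effect
# about three times the remaining categories, feeding elevated, and
# emotion/social below the overall mean.  The global mean PVE under these
# defaults is ~9.5%.
DEFAULT_CATEGORY_N = {
    "courtship": 124,
    "feeding": 11,
    "emotion": 180,
    "social": 150,
    "activity": 160,
    "learning_memory": 120,
    "aggression": 60,
    "olfaction": 70,
    "stress": 72,
    "mating": 60,
}
DEFAULT_CATEGORY_MEAN_PVE = {
    "courtship": 23.0,
    "feeding": 17.0,
    "emotion": 5.5,
    "social": 6.5,
    "activity": 8.5,
    "learning_memory": 8.5,
    "aggression": 8.5,
    "olfaction": 8.5,
    "stress": 8.5,
    "mating": 8.5,
}

_TAXON_CLASSES = ("mammal", "bird", "fish", "insect", "crustacean")


@dataclass
class QtlSimConfig:
    """Configuration for the synthetic compiled-QTL table.

    ``mean_pve`` sets the expected effect size per category; draws are
    exponential (mean-compensated for the (0, 100] truncation).
    ``divergence_effect_slope`` is the fold change in mean PVE per decade
    of years diverged around the panel-wide centre (1.0 = no divergence
    effect); per-record means are renormalized within each category so
    the configured category means are preserved.  The multiplicative
    trend induces the positive divergence/effect-size correlation and
    the larger effects seen in interspecific crosses.
    """

    categories: tuple[str, ...] = tuple(DEFAULT_CATEGORY_N)
    n_loci_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_N)
    )
    mean_pve: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MEAN_PVE)
    )
    sample_size_range: tuple[int, int] = (50, 500)
    fraction_interspecific: float = 0.3
    # log10(year) bounds for intra- and interspecific crosses
    intraspecific_years_range: tuple[float, float] = (1e4, 1e6)
    interspecific_years_range: tuple[float, float] = (1e6, 5e8)
    generation_time_range: tuple[float, float] = (0.1, 5.0)  # years/generation
    divergence_effect_slope: float = 1.9  # fold change in mean PVE per decade
    loci_per_study: int = 9
    fraction_lod_reported: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for cat in self.categories:
            n = self.n_loci_per_category.get(cat, 0)
            if n < 0:
                raise ConfigError(f"negative locus count for {cat!r}")
            if self.mean_pve.get(cat, 1.0) <= 0:
                raise ConfigError(f"non-positive mean PVE for {cat!r}")
        if not 0.0 <= self.fraction_interspecific <= 1.0:
            raise ConfigError("fraction_interspecific must be in [0, 1]")
        for lo, hi in (
            self.intraspecific_years_range,
            self.interspecific_years_range,
            self.generation_time_range,
        ):
            if lo <= 0 or hi < lo:
                raise ConfigError("divergence/generation ranges must be positive and ordered")
        if self.sample_size_range[0] < 2 or self.sample_size_range[1] < self.sample_size_range[0]:
            raise ConfigError("sample_size_range must be ordered with minimum >= 2")
        if self.loci_per_study < 1:
            raise ConfigError("loci_per_study must be >= 1")
        if self.divergence_effect_slope <= 0:
            raise ConfigError("divergence_effect_slope must be > 0 (1.0 = flat)")


def _compensated_scale(target_mean: float) -> float:
    """Exponential scale whose truncation to (0, 100] has the target mean.

    Truncating an exponential at 100 pulls its mean down; solving for the
    underlying scale keeps the generator's contract that simulated
    category means converge to the configured values.
    """
    from scipy.optimize import brentq

    # a (0, 100]-truncated exponential cannot exceed mean 50 (uniform
    # limit); clamp just below so the solver stays bracketed
    target_mean = min(max(target_mean, 1e-3), 49.0)

    def trunc_mean(m: float) -> float:
        z = 100.0 / m
        if z > 700:
            return m
        return m - 100.0 * math.exp(-z) / (1.0 - math.exp(-z))

    if trunc_mean(target_mean) >= target_mean - 1e-12:
        return target_mean
    return brentq(lambda m: trunc_mean(m) - target_mean, target_mean, 1e6)


def _truncated_exponential(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Draws in (0, 100] whose expectation equals ``mean`` (exponential body)."""
    scale = _compensated_scale(mean)
    out = rng.exponential(scale, size)
    bad = (out <= 0) | (out > 100.0)
    while bad.any():
        out[bad] = rng.exponential(scale, int(bad.sum()))
        bad = (out <= 0) | (out > 100.0)
    return out


def gen_qtl_table(config: QtlSimConfig | None = None) -> pd.DataFrame:
    """Simulate a compiled table of significant behavioral QTL.

    Returns a DataFrame in the package's QTL CSV schema (see
    :mod:`behavarch.io`): one row per locus with ``study_id``, cross
    parents, ``behavioral_category``, ``effect_size_pve``, ``lod`` or
    ``neglog10_p``, ``sample_size``, ``generations_diverged``,
    ``years_diverged``, ``cross_type`` and a genome location.

    Loci are grouped into studies; sample size, species pair and
    divergence are study-level properties shared by the loci of a study.
    """
    config = config or QtlSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows = []
    study_counter = 0
    for cat in config.categories:
        n = config.n_loci_per_category.get(cat, 0)
        if n == 0:
            continue
        n_studies = max(1, round(n / config.loci_per_study))
        # multinomial split of loci over studies (each study >= 1 locus)
        sizes = np.full(n_studies, n // n_studies)
        sizes[: n % n_studies] += 1
        for size in sizes:
            study_counter += 1
            sid = f"study{study_counter:04d}"
            inter = rng.random() < config.fraction_interspecific
            lo, hi = (
                config.interspecific_years_range
                if inter
                else config.intraspecific_years_range
            )
            years = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            gen_time = 10 ** rng.uniform(
                math.log10(config.generation_time_range[0]),
                math.log10(config.generation_time_range[1]),
            )
            generations = years / gen_time
            n_ind = int(rng.integers(config.sample_size_range[0],
                                     config.sample_size_range[1] + 1))
            taxon = _TAXON_CLASSES[rng.integers(0, len(_TAXON_CLASSES))]
            genus = f"genus{study_counter:03d}"
            species_a = f"{genus}_sp1"
            species_b = f"{genus}_sp2" if inter else species_a
            for k in range(size):
                rows.append(
                    dict(
                        study_id=sid,
                        species_a=species_a,
                        species_b=species_b,
                        taxon_class=taxon,
                        behavioral_category=cat,
                        trait_name=f"{cat}_trait_{sid}",
                        sample_size=n_ind,
                        generations_diverged=generations,
                        years_diverged=years,
                        cross_type="interspecific" if inter else "intraspecific",
                        chrom=f"lg{int(rng.integers(1, 11))}",
                        pos=int(rng.integers(1, 100_000_001)),
                    )
                )

    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=[
                "study_id", "species_a", "species_b", "taxon_class",
                "behavioral_category", "trait_name", "effect_size_pve",
                "lod", "neglog10_p", "sample_size", "generations_diverged",
                "years_diverged", "cross_type", "chrom", "pos",
            ]
        )
        table.attrs["seed"] = config.seed
        return table

    # effect sizes: exponential with a multiplicative divergence effect on
    # the category mean, renormalized so each category keeps its
    # configured mean
    log_years = np.log10(table["years_diverged"].to_numpy())
    centre = log_years.mean()
    means = np.array(
        [config.mean_pve[c] for c in table["behavioral_category"]], dtype=float
    )
    means = means * config.divergence_effect_slope ** (log_years - centre)
    cats = table["behavioral_category"].to_numpy()
    for cat in config.categories:
        idx = cats == cat
        if idx.any():
            means[idx] *= config.mean_pve[cat] / means[idx].mean()
    pve = np.empty(len(table))
    for i, m in enumerate(means):
        pve[i] = _truncated_exponential(rng, m, 1)[0]
    table["effect_size_pve"] = pve

    # significance: larger effects at larger samples reach larger LOD scores;
    # a fraction of studies report -log10 P directly instead of LOD
    lod = 3.0 + rng.exponential(2.0, len(table))
    report_lod = rng.random(len(table)) < config.fraction_lod_reported
    table["lod"] = np.where(report_lod, lod, np.nan)
    from .qtl_meta import lod_to_neglog10p  # local import avoids a cycle

    table["neglog10_p"] = np.where(
        report_lod, np.nan, np.round(lod_to_neglog10p(lod), 4)
    )
    order = [
        "study_id", "species_a", "species_b", "taxon_class",
        "behavioral_category", "trait_name", "effect_size_pve", "lod",
        "neglog10_p", "sample_size", "generations_diverged",
        "years_diverged", "cross_type", "chrom", "pos",
    ]
    table = table[order]
    table.attrs["seed"] = config.seed
    return table


# ---------------------------------------------------------------------------
# genotype / phenotype panel simulation
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Additive causal architecture of one simulated trait.

    ``causal_snps`` indexes columns of the panel; ``betas`` are per-allele
    effects.  When ``betas`` is None, effects are drawn with variance
    inversely proportional to the dosage variance of each causal SNP
    (standardized effect sizes), the assumption under which a single
    relatedness-matrix variance component captures the genetic variance.
    ``h2`` is the target fraction of phenotypic variance that is genetic.
    """

    name: str
    causal_snps: np.ndarray
    betas: np.ndarray | None = None
    h2: float = 0.5

    def __post_init__(self) -> None:
        self.causal_snps = np.asarray(self.causal_snps, dtype=int)
        if self.betas is not None:
            self.betas = np.asarray(self.betas, dtype=float)
            if self.betas.shape != self.causal_snps.shape:
                raise ConfigError("betas and causal_snps must have equal length")
        if not 0.0 <= self.h2 < 1.0:
            raise ConfigError(f"target h2 must be in [0, 1); got {self.h2}")


@dataclass
class PanelSimConfig:
    """Configuration for a synthetic inbred-line genotype/phenotype panel."""

    n_lines: int = 200
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbred: bool = True
    traits: list[TraitArchitecture] = field(default_factory=list)
    pleiotropy_structure: str | None = None  # None, "fork" or "chain"
    chain_coeff: float = 1.0
    chain_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2 or self.n_snps < 1:
            raise ConfigError("need n_lines >= 2 and n_snps >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must satisfy 0 < low <= high <= 0.5")
        if self.pleiotropy_structure not in (None, "fork", "chain"):
            raise ConfigError("pleiotropy_structure must be None, 'fork' or 'chain'")
        if not math.isfinite(self.chain_coeff):
            raise ConfigError("chain coefficient must be finite")
        if self.chain_noise_sd < 0:
            raise ConfigError("chain_noise_sd must be >= 0")
        for t in self.traits:
            if len(t.causal_snps) and (
                t.causal_snps.min() < 0 or t.causal_snps.max() >= self.n_snps
            ):
                raise ConfigError(f"causal SNP index out of range for trait {t.name!r}")


_CHROMS = ("2L", "2R", "3L", "3R")


def gen_genotypes(config: PanelSimConfig) -> GenotypePanel:
    """Simulate a biallelic SNP panel of inbred (or outbred) lines.

    Each SNP draws an alternate-allele frequency uniformly from
    ``maf_range``; dosages are 2 x Bernoulli(p) for inbred lines (every
    line homozygous) or Binomial(2, p) otherwise.  SNPs are laid out on
    four autosomal arms with increasing positions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    if config.inbred:
        dosages = 2.0 * (rng.random((config.n_lines, config.n_snps)) < p)
    else:
        dosages = rng.binomial(2, p, size=(config.n_lines, config.n_snps)).astype(float)

    per_chrom = int(np.ceil(config.n_snps / len(_CHROMS)))
    chroms = np.repeat(_CHROMS, per_chrom)[: config.n_snps]
    pos = np.concatenate(
        [np.arange(1, (chroms == c).sum() + 1) * 1000 for c in _CHROMS]
    )[: config.n_snps]
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "a1": "A",
            "a2": "T",
        },
        index=pd.Index([f"snp{i:06d}" for i in range(config.n_snps)], name="snp_id"),
    )
    line_ids = [f"line{i:04d}" for i in range(config.n_lines)]
    return GenotypePanel(
        line_ids=line_ids,
        snps=snps,
        dosages=dosages,
        inbred=config.inbred,
        metadata={"seed": config.seed, "drawn_freqs": p},
    )


def _draw_standardized_betas(
    rng: np.random.Generator, panel: GenotypePanel, idx: np.ndarray
) -> np.ndarray:
    p = panel.allele_freqs()[idx]
    het = 2.0 * p * (1.0 - p)
    if panel.inbred:
        het = het * 2.0  # dosage variance of {0,2} genotypes is 4p(1-p)
    het = np.maximum(het, 1e-8)
    return rng.standard_normal(len(idx)) / np.sqrt(het)


def gen_phenotypes(panel: GenotypePanel, config: PanelSimConfig) -> pd.DataFrame:
    """Simulate per-line trait values on a genotype panel.

    Each trait is additive, ``y = X[:, causal] @ beta + e``, with the
    Gaussian noise scaled so that the realized genetic-variance fraction
    matches the trait's target ``h2``.  Under ``pleiotropy_structure ==
    "chain"`` every trait after the first is generated from its
    predecessor (``y_k = a * y_{k-1} + noise``) rather than from genotype,
    the mediated pattern the directionality test is designed to detect.

    Returns a lines x traits DataFrame; the seed is stored in ``attrs``.
    """
    config.validate()
    if not config.traits:
        raise ConfigError("no traits configured")
    rng = np.random.default_rng(config.seed + 1)
    n = panel.n_lines
    out = {}
    prev = None
    # under "fork", traits with identical causal sets share one drawn beta
    # vector, so the pleiotropy is real rather than coincidental
    shared_betas: dict[tuple, np.ndarray] = {}
    genetic: dict[str, np.ndarray] = {}

    def standalone(trait: TraitArchitecture, betas: np.ndarray | None):
        if betas is None:
            betas = _draw_standardized_betas(rng, panel, trait.causal_snps)
        X = panel.dosages[:, trait.causal_snps]
        X = np.where(np.isfinite(X), X, 0.0)
        g = X @ betas
        var_g = g.var(ddof=1)
        if var_g <= 0:
            raise ConfigError(
                f"trait {trait.name!r}: causal SNPs carry no genetic variance"
            )
        e_sd = math.sqrt(var_g * (1.0 - trait.h2) / trait.h2)
        return g + rng.normal(0.0, e_sd, n), g

    for k, trait in enumerate(config.traits):
        if config.pleiotropy_structure == "chain" and k > 0:
            # mediated trait: sees the genotype only through its
            # predecessor, plus its own independent determinants — its own
            # architecture when configured, otherwise pure noise.  (A
            # downstream trait with no independent determinants has effect
            # sizes exactly proportional to its mediator's and is
            # undetectable by the directionality test.)
            if trait.h2 == 0.0 or len(trait.causal_snps) == 0:
                own = rng.normal(0.0, config.chain_noise_sd, n)
                g = np.full(n, np.nan)
            else:
                own, g = standalone(trait, trait.betas)
            y = config.chain_coeff * prev + own
        elif trait.h2 == 0.0 or len(trait.causal_snps) == 0:
            y = rng.standard_normal(n)
            g = np.zeros(n)
        else:
            betas = trait.betas
            if betas is None and config.pleiotropy_structure == "fork":
                key = tuple(trait.causal_snps.tolist())
                if key not in shared_betas:
                    shared_betas[key] = _draw_standardized_betas(
                        rng, panel, trait.causal_snps
                    )
                betas = shared_betas[key]
            y, g = standalone(trait, betas)
        out[trait.name] = y
        genetic[trait.name] = g
        prev = y
    table = pd.DataFrame(out, index=pd.Index(panel.line_ids, name="line_id"))
    table.attrs["seed"] = config.seed
    table.attrs["pleiotropy_structure"] = config.pleiotropy_structure
    # realized additive genetic values (NaN for chain traits, whose genetic
    # component is inherited through the mediator)
    table.attrs["genetic_values"] = pd.DataFrame(
        genetic, index=table.index
    )
    return table


def fork_pair_config(
    n_lines: int = 2000,
    n_snps: int = 1500,
    n_causal: int = 60,
    h2: float = 0.92,
    seed: int = 0,
) -> PanelSimConfig:
    """Two traits driven independently by the same causal SNPs (P1 <- G -> P2).

    The symmetric pleiotropy pattern: both traits load on the shared loci
    with their own independent noise, so neither trait mediates the other.
    """
    causal = np.arange(n_causal)
    return PanelSimConfig(
        n_lines=n_lines,
        n_snps=n_snps,
        traits=[
            TraitArchitecture("p1", causal, h2=h2),
            TraitArchitecture("p2", causal, h2=h2),
        ],
        pleiotropy_structure="fork",
        seed=seed,
    )


def chain_pair_config(
    n_lines: int = 2000,
    n_snps: int = 1500,
    n_causal: int = 60,
    h2: float = 0.92,
    own_n_causal: int = 60,
    own_h2: float = 0.92,
    chain_coeff: float = 0.35,
    seed: int = 0,
) -> PanelSimConfig:
    """Mediated trait pair (G -> P1 -> P2 <- own loci).

    P1 has ``n_causal`` loci of strong effect; P2 sees those loci only
    through P1 (scaled by ``chain_coeff``) and additionally carries its
    own disjoint architecture of ``own_n_causal`` loci — the independent
    determinants that give the mediated trait a hit set of its own.
    """
    causal = np.arange(n_causal)
    own = np.arange(n_causal, n_causal + own_n_causal)
    return PanelSimConfig(
        n_lines=n_lines,
        n_snps=n_snps,
        traits=[
            TraitArchitecture("p1", causal, h2=h2),
            TraitArchitecture("p2", own, h2=own_h2),
        ],
        pleiotropy_structure="chain",
        chain_coeff=chain_coeff,
        seed=seed,
    )
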