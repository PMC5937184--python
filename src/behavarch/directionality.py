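"""Trait-pair directionality test on cross-correlated GWAS effect sizes.

Discriminates a mediated architecture (G -> P1 -> P2: the genotype moves
trait 2 only through trait 1) from symmetric pleiotropy (P1 <- G -> P2).
For traits x and y let s1/s2 be the SNPs significant for x/y.  Four
effect-size vectors are read off the effect matrix: xx and xy (betas of
x and y at s1), yy and yx (betas of y and x at s2).  With Spearman
correlations x_cor = rho(xx, xy) and y_cor = rho(yy, yx), the statistic

    D = |1 - |x_cor - y_cor||

is near 0 exactly when one cross-correlation is strong and the other
absent — the asymmetry a mediated pair produces (at trait x's own hits
both traits respond; at trait y's hits, which reached significance
through noise, trait x does not).  SMALL D therefore signals
directionality.  Significance comes from independently permuting all
four vectors and counting how often the observed D exceeds the permuted
one (strict rule: ties favor the null); P-values are Bonferroni-adjusted
over the tested pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import DegenerateInputError, ScreenedOutError
from .gwas import EffectMatrix

#: a trait enters pairwise testing only with strictly more hits than this
MIN_HITS = 3
SCREEN_HIGH = 0.5
SCREEN_LOW = 0.1


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho on pairwise-complete observations (midranks for ties)."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return float("nan")
    ra = st.rankdata(a[mask])
    rb = st.rankdata(b[mask])
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise DegenerateInputError("constant vector: Spearman correlation undefined")
    return float(np.corrcoef(ra, rb)[0, 1])


def pair_vectors(
    matrix: EffectMatrix, trait_x: str, trait_y: str, min_hits: int = MIN_HITS
):
    """Extract (xx, xy, yy, yx) for a trait pair from the effect matrix.

    Raises :class:`ScreenedOutError` unless both traits have strictly
    more than ``min_hits`` significant SNPs.
    """
    for t in (trait_x, trait_y):
        if t not in matrix.hits:
            raise KeyError(f"trait {t!r} has no recorded hit set")
        if len(matrix.hits[t]) <= min_hits:
            raise ScreenedOutError(
                f"trait {t!r} has {len(matrix.hits[t])} hits; needs > {min_hits}"
            )
    s1 = sorted(matrix.hits[trait_x])
    s2 = sorted(matrix.hits[trait_y])
    xx = matrix.betas.loc[s1, trait_x].to_numpy(dtype=float)
    xy = matrix.betas.loc[s1, trait_y].to_numpy(dtype=float)
    yy = matrix.betas.loc[s2, trait_y].to_numpy(dtype=float)
    yx = matrix.betas.loc[s2, trait_x].to_numpy(dtype=float)
    return xx, xy, yy, yx


def d_statistic(x_cor: float, y_cor: float) -> float:
    """``D = |1 - |x_cor - y_cor||`` for a pair of cross-correlations."""
    return abs(1.0 - abs(x_cor - y_cor))


def directionality_D(xx, xy, yy, yx) -> tuple[float, float, float]:
    """The pair's cross-correlations and the directionality statistic.

    Returns ``(x_cor, y_cor, D)`` with ``D = |1 - |x_cor - y_cor||``;
    D lies in [0, 1] and values near 0 indicate an asymmetric
    (putatively mediated) relationship.
    """
    xx, xy, yy, yx = (np.asarray(v, dtype=float) for v in (xx, xy, yy, yx))
    if min(xx.size, xy.size, yy.size, yx.size) < 4:
        raise ValueError("each effect-size vector needs length >= 4")
    x_cor = _spearman(xx, xy)
    y_cor = _spearman(yy, yx)
    return x_cor, y_cor, d_statistic(x_cor, y_cor)


def screen_pair(
    x_cor: float,
    y_cor: float,
    high: float = SCREEN_HIGH,
    low: float = SCREEN_LOW,
) -> bool:
    """Asymmetry screen: one |rho| above ``high``, the other below ``low``.

    Absolute values are compared, so a strongly negative correlation
    paired with a null one passes.
    """
    if not (np.isfinite(x_cor) and np.isfinite(y_cor)):
        raise ValueError("both correlations must be defined")
    a, b = abs(x_cor), abs(y_cor)
    return (a > high and b < low) or (b > high and a < low)


def _permuted_rank_corrs(
    ranks_a: np.ndarray, ranks_b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Spearman rho between independently permuted copies of two vectors.

    Permuting a vector permutes its ranks, so the null correlations are
    Pearson correlations of shuffled rank vectors, which vectorizes to
    one matrix multiplication per vector pair.
    """
    L = ranks_a.size
    za = (ranks_a - ranks_a.mean()) / ranks_a.std()
    zb = (ranks_b - ranks_b.mean()) / ranks_b.std()
    Pa = np.argsort(rng.random((n_perm, L)), axis=1)
    Pb = np.argsort(rng.random((n_perm, L)), axis=1)
    return (za[Pa] * zb[Pb]).mean(axis=1)


def exact_permutation_null(xx, xy, yy, yx) -> np.ndarray:
    """All distinct values of the permuted D statistic (tiny vectors only).

    The permutation distribution of a Spearman correlation between two
    independently shuffled vectors depends only on their relative order,
    so it has L! atoms; the D null is the outer combination of the two
    correlation nulls.
    """
    import itertools

    def corr_null(a, b):
        mask = np.isfinite(a) & np.isfinite(b)
        a, b = a[mask], b[mask]
        ra, rb = st.rankdata(a), st.rankdata(b)
        za = (ra - ra.mean()) / ra.std()
        zb = (rb - rb.mean()) / rb.std()
        return np.array(
            [np.mean(za[list(pi)] * zb) for pi in itertools.permutations(range(a.size))]
        )

    cx = corr_null(np.asarray(xx, float), np.asarray(xy, float))
    cy = corr_null(np.asarray(yy, float), np.asarray(yx, float))
    d = np.abs(1.0 - np.abs(cx[:, None] - cy[None, :]))
    return d.ravel()


def permutation_p(
    xx,
    xy,
    yy,
    yx,
    n_perm: int = 1000,
    seed: int | None = None,
    joint: bool = False,
) -> tuple[float, float]:
    """Permutation P-value for the directionality statistic.

    Each iteration independently permutes all four effect-size vectors,
    recomputes the two cross-correlations and D, and the P-value is the
    fraction of iterations whose permuted D falls strictly below the
    observed one (``sum(D_obs > D_perm) / n_perm``) — small P means the
    observed D is unusually close to 0.  ``joint=True`` instead applies
    one shared permutation to each hit set's two vectors, preserving the
    SNP alignment within s1 and s2.

    For vectors so short that fewer than ``n_perm`` distinct relative
    orderings exist, the exact enumeration null is used instead (with a
    warning).  Returns ``(D_observed, p_value)``.
    """
    xx, xy, yy, yx = (np.asarray(v, dtype=float) for v in (xx, xy, yy, yx))
    x_cor, y_cor, d_obs = directionality_D(xx, xy, yy, yx)
    rng = np.random.default_rng(seed)

    n_distinct = math.factorial(min(xx.size, 20)) * math.factorial(min(yy.size, 20))
    if not joint and n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct permutations; using exact enumeration",
            RuntimeWarning,
            stacklevel=2,
        )
        null = exact_permutation_null(xx, xy, yy, yx)
        return d_obs, float(np.mean(d_obs > null))

    has_nan = any(~np.isfinite(v).all() for v in (xx, xy, yy, yx))
    if has_nan or joint:
        # general path: re-rank after permutation (pairwise-complete)
        pd_vals = np.empty(n_perm)
        for b in range(n_perm):
            if joint:
                p1 = rng.permutation(xx.size)
                p2 = rng.permutation(yy.size)
                pxc = _spearman(xx[p1], xy[p1])
                pyc = _spearman(yy[p2], yx[p2])
            else:
                pxc = _spearman(rng.permutation(xx), rng.permutation(xy))
                pyc = _spearman(rng.permutation(yy), rng.permutation(yx))
            pd_vals[b] = abs(1.0 - abs(pxc - pyc))
    else:
        rx1, rx2 = st.rankdata(xx), st.rankdata(xy)
        ry1, ry2 = st.rankdata(yy), st.rankdata(yx)
        cx = _permuted_rank_corrs(rx1, rx2, n_perm, rng)
        cy = _permuted_rank_corrs(ry1, ry2, n_perm, rng)
        pd_vals = np.abs(1.0 - np.abs(cx - cy))
    p = float(np.sum(d_obs > pd_vals) / n_perm)
    return d_obs, p


@dataclass
class TraitPairResult:
    trait_x: str
    trait_y: str
    n_s1: int
    n_s2: int
    x_cor: float
    y_cor: float
    D: float
    p_perm: float
    p_adjusted: float = float("nan")
    passed_screen: bool = False
    ambiguous_direction: bool = False


def test_trait_pair(
    matrix: EffectMatrix,
    trait_x: str,
    trait_y: str,
    n_perm: int = 1000,
    seed: int | None = None,
    min_hits: int = MIN_HITS,
    screen_high: float = SCREEN_HIGH,
    screen_low: float = SCREEN_LOW,
    joint: bool = False,
) -> TraitPairResult:
    """Run the full directionality test for one ordered trait pair."""
    xx, xy, yy, yx = pair_vectors(matrix, trait_x, trait_y, min_hits=min_hits)
    x_cor, y_cor, d = directionality_D(xx, xy, yy, yx)
    _, p = permutation_p(xx, xy, yy, yx, n_perm=n_perm, seed=seed, joint=joint)
    return TraitPairResult(
        trait_x=trait_x,
        trait_y=trait_y,
        n_s1=len(xx),
        n_s2=len(yy),
        x_cor=x_cor,
        y_cor=y_cor,
        D=d,
        p_perm=p,
        passed_screen=screen_pair(x_cor, y_cor, high=screen_high, low=screen_low),
    )


def adjust_and_report(
    results: list[TraitPairResult], n_tests: int | None = None
) -> pd.DataFrame:
    """Bonferroni-adjust permutation P-values and tabulate the pairs.

    ``n_tests`` defaults to the number of pairs actually tested.  The
    returned table is sorted by adjusted P; ``significant`` combines the
    adjusted P < 0.05 rule with the asymmetry screen, and pairs whose
    reverse ordering also passed the screen are flagged
    ``ambiguous_direction`` rather than silently dropped.
    """
    if not results:
        raise ValueError("no tested pairs to report")
    n_tests = n_tests if n_tests is not None else len(results)
    screened = {(r.trait_x, r.trait_y) for r in results if r.passed_screen}
    rows = []
    for r in results:
        r.p_adjusted = min(1.0, r.p_perm * n_tests)
        r.ambiguous_direction = (
            r.passed_screen and (r.trait_y, r.trait_x) in screened
        )
        rows.append(
            dict(
                trait_x=r.trait_x,
                trait_y=r.trait_y,
                n_s1=r.n_s1,
                n_s2=r.n_s2,
                x_cor=r.x_cor,
                y_cor=r.y_cor,
                D=r.D,
                p_perm=r.p_perm,
                p_adjusted=r.p_adjusted,
                passed_screen=r.passed_screen,
                ambiguous_direction=r.ambiguous_direction,
                significant=(r.p_adjusted < 0.05) and r.passed_screen,
            )
        )
    out = pd.DataFrame(rows).sort_values(
        ["p_adjusted", "D"], kind="stable"
    ).reset_index(drop=True)
    return out
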