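"""Gibbs sampler for the Gaussian linear mixed model, with DIC ranking.

Model: ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, s2_k I)`` and
``e ~ N(0, s2_e I)``.  Priors: diffuse normal on the fixed effects and
inverse-gamma (shape 0.001, scale 0.001) on every variance component —
weakly informative, the conventional default for animal-model style mixed
models.  All full conditionals are conjugate, so sampling is a plain
Gibbs scheme: a blocked multivariate-normal draw of (b, u) followed by
inverse-gamma draws of the variances.

Convergence is summarized by the Gelman-Rubin potential scale reduction
factor over independent chains, and models are compared with the deviance
information criterion DIC = Dbar + pD, pD = Dbar - D(posterior mean),
computed from the conditional (residual-level) deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .qtl_meta import RANDOM_EFFECT_TERMS, _prepare_covariates

_PRIOR_SHAPE = 0.001
_PRIOR_SCALE = 0.001
_BETA_PRIOR_VAR = 1e8

#: the candidate random-effect structures ranked in the model comparison —
#: every nonempty combination of the three study-level effects
ALL_RANDOM_STRUCTURES: tuple[tuple[str, ...], ...] = (
    ("sample_size",),
    ("generations",),
    ("cross_type",),
    ("sample_size", "generations"),
    ("sample_size", "cross_type"),
    ("generations", "cross_type"),
    ("sample_size", "generations", "cross_type"),
)


@dataclass
class BayesLmmFit:
    fixed_effects: pd.DataFrame  # index: term; columns: mean, hpd_lower, hpd_upper
    variance_components: pd.DataFrame
    dic: float
    psrf: dict[str, float]
    settings: dict
    random_structure: tuple[str, ...]
    reference_category: str
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(v <= 1.1 for v in self.psrf.values() if np.isfinite(v))


def _design_matrices(records: pd.DataFrame, random_structure):
    df = _prepare_covariates(records)
    cats = sorted(df["behavioral_category"].unique())
    ref = cats[0]
    X_cols = ["(Intercept)"] + [f"category[{c}]" for c in cats[1:]]
    X = np.ones((len(df), len(X_cols)))
    for j, c in enumerate(cats[1:], start=1):
        X[:, j] = (df["behavioral_category"] == c).astype(float)

    studies = pd.Categorical(df["study_id"])
    S = np.zeros((len(df), len(studies.categories)))
    S[np.arange(len(df)), studies.codes] = 1.0

    z_blocks: list[tuple[str, np.ndarray]] = [("study", S)]
    for term in random_structure:
        if term == "sample_size":
            z_blocks.append(("sample_size", S * df["sample_size_z"].to_numpy()[:, None]))
        elif term == "generations":
            z_blocks.append(("generations", S * df["generations_z"].to_numpy()[:, None]))
        elif term == "cross_type":
            ct = pd.Categorical(df["cross_type"])
            C = np.zeros((len(df), len(ct.categories)))
            C[np.arange(len(df)), ct.codes] = 1.0
            z_blocks.append(("cross_type", C))
        else:
            raise ValueError(
                f"unknown random-effect term {term!r}; expected one of {RANDOM_EFFECT_TERMS}"
            )
    return df, X, X_cols, z_blocks, ref


def _run_chain(y, W, p, block_slices, n_iter, burn_in, thin, rng):
    """One Gibbs chain; returns kept draws of (theta, variances, deviance)."""
    n, K = len(y), len(block_slices)
    m = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    s2 = np.full(K, max(y.var(), 1e-6) / (K + 1.0))
    s2_e = max(y.var(), 1e-6) / 2.0

    n_keep = (n_iter - burn_in) // thin
    theta_draws = np.empty((n_keep, m))
    var_draws = np.empty((n_keep, K + 1))
    dev_draws = np.empty(n_keep)
    kept = 0

    prior_prec = np.empty(m)
    prior_prec[:p] = 1.0 / _BETA_PRIOR_VAR

    from scipy.linalg import cho_factor, solve_triangular

    M = np.empty_like(WtW)
    for it in range(n_iter):
        for k, sl in enumerate(block_slices):
            prior_prec[sl] = 1.0 / s2[k]
        np.multiply(WtW, 1.0 / s2_e, out=M)
        M[np.diag_indices_from(M)] += prior_prec
        L, _ = cho_factor(M, lower=True, overwrite_a=False, check_finite=False)
        half = solve_triangular(L, Wty / s2_e, lower=True, check_finite=False)
        z = rng.standard_normal(m)
        theta = solve_triangular(L.T, half + z, lower=False, check_finite=False)

        resid = y - W @ theta
        rss = float(resid @ resid)
        s2_e = 1.0 / rng.gamma(_PRIOR_SHAPE + n / 2.0, 1.0 / (_PRIOR_SCALE + rss / 2.0))
        for k, sl in enumerate(block_slices):
            u = theta[sl]
            q = sl.stop - sl.start
            s2[k] = 1.0 / rng.gamma(
                _PRIOR_SHAPE + q / 2.0, 1.0 / (_PRIOR_SCALE + float(u @ u) / 2.0)
            )

        if it >= burn_in and (it - burn_in) % thin == 0:
            theta_draws[kept] = theta
            var_draws[kept, :K] = s2
            var_draws[kept, K] = s2_e
            dev_draws[kept] = n * np.log(2 * np.pi * s2_e) + rss / s2_e
            kept += 1
    return theta_draws[:kept], var_draws[:kept], dev_draws[:kept]


def fit_bayes_lmm(
    records: pd.DataFrame,
    random_structure: tuple[str, ...] = ("sample_size", "generations"),
    burn_in: int = 10_000,
    n_iter: int = 300_000,
    thin: int = 10,
    n_chains: int = 5,
    seed: int | None = None,
) -> BayesLmmFit:
    """Bayesian linear mixed model of PVE on behavioral category.

    Fixed effect: category (treatment-coded).  Random effects: a study
    intercept plus the requested study-level terms (random slope of
    scaled sample size and/or log10 generations by study; random
    intercept per cross type).  Defaults run 300,000 iterations with a
    10,000-iteration burn-in, thinned by 10, over 5 independent chains.

    Returns posterior means with 95% highest-posterior-density intervals
    per fixed-effect level, variance-component posteriors, DIC, and the
    Gelman-Rubin PSRF per parameter (a warning is attached when any PSRF
    exceeds 1.1).  Deterministic given ``seed``.
    """
    if records["behavioral_category"].nunique() < 2:
        raise InsufficientDataError("need >= 2 behavioral categories")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")

    df, X, X_cols, z_blocks, ref = _design_matrices(records, random_structure)
    y = df["effect_size_pve"].to_numpy(dtype=float)
    p = X.shape[1]
    mats = [X] + [Z for _, Z in z_blocks]
    W = np.concatenate(mats, axis=1)
    block_slices = []
    start = p
    for _, Z in z_blocks:
        block_slices.append(slice(start, start + Z.shape[1]))
        start += Z.shape[1]

    theta_chains, var_chains, dev_chains = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(None if seed is None else [int(seed), c])
        t, v, d = _run_chain(y, W, p, block_slices, n_iter, burn_in, thin, rng)
        theta_chains.append(t)
        var_chains.append(v)
        dev_chains.append(d)
    theta = np.stack(theta_chains)  # chains x draws x m
    vars_ = np.stack(var_chains)
    dev = np.stack(dev_chains)

    var_names = [f"var[{name}]" for name, _ in z_blocks] + ["var[residual]"]

    # posterior summaries of the fixed effects
    fe_rows = {}
    psrf = {}
    for j, name in enumerate(X_cols):
        draws = theta[:, :, j]
        lo, hi = _hpd(draws.ravel(), 0.95)
        fe_rows[name] = {"mean": float(draws.mean()), "hpd_lower": lo, "hpd_upper": hi}
        psrf[name] = _psrf(draws)
    fe = pd.DataFrame(fe_rows).T[["mean", "hpd_lower", "hpd_upper"]]

    vc_rows = {}
    for k, name in enumerate(var_names):
        draws = vars_[:, :, k]
        lo, hi = _hpd(draws.ravel(), 0.95)
        vc_rows[name] = {"mean": float(draws.mean()), "hpd_lower": lo, "hpd_upper": hi}
        psrf[name] = _psrf(draws)
    vc = pd.DataFrame(vc_rows).T[["mean", "hpd_lower", "hpd_upper"]]

    # DIC from the conditional deviance
    d_bar = float(dev.mean())
    theta_bar = theta.reshape(-1, theta.shape[-1]).mean(axis=0)
    s2e_bar = float(vars_[:, :, -1].mean())
    resid = y - W @ theta_bar
    d_hat = len(y) * np.log(2 * np.pi * s2e_bar) + float(resid @ resid) / s2e_bar
    dic = 2 * d_bar - d_hat

    warn_list = []
    bad = {k: v for k, v in psrf.items() if np.isfinite(v) and v > 1.1}
    if bad and n_chains > 1:
        msg = f"PSRF > 1.1 for {sorted(bad)}; chains may not have converged"
        warn_list.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    return BayesLmmFit(
        fixed_effects=fe,
        variance_components=vc,
        dic=float(dic),
        psrf=psrf,
        settings=dict(
            burn_in=burn_in, n_iter=n_iter, thin=thin, n_chains=n_chains, seed=seed
        ),
        random_structure=tuple(random_structure),
        reference_category=ref,
        warnings=warn_list,
    )


def _hpd(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the (sorted) draws."""
    x = np.sort(draws)
    n = x.size
    k = max(1, int(np.floor(prob * n)))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _psrf(draws: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction over chains (rows)."""
    m, n = draws.shape
    if m < 2 or n < 2:
        return float("nan")
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return float("nan")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rank_models_by_dic(
    records: pd.DataFrame,
    candidate_random_structures=ALL_RANDOM_STRUCTURES,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit a Bayesian LMM per candidate random structure and rank by DIC.

    Returns a DataFrame sorted ascending by DIC (best model first) with
    columns ``random_structure``, ``dic``, ``converged`` and ``fit``
    (the full :class:`BayesLmmFit`, or None for candidates whose fit
    raised; their error text is kept in ``error`` instead of aborting
    the ranking).
    """
    if not candidate_random_structures:
        raise ValueError("need >= 1 candidate random structure")
    rows = []
    for structure in candidate_random_structures:
        try:
            fit = fit_bayes_lmm(records, tuple(structure), **fit_kwargs)
            rows.append(
                dict(
                    random_structure=tuple(structure),
                    dic=fit.dic,
                    converged=fit.converged,
                    fit=fit,
                    error=None,
                )
            )
        except Exception as exc:  # ranking must survive individual failures
            rows.append(
                dict(
                    random_structure=tuple(structure),
                    dic=float("inf"),
                    converged=False,
                    fit=None,
                    error=str(exc),
                )
            )
    out = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    return out
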