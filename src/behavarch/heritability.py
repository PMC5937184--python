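"""SNP heritability: relatedness matrix construction and REML estimation.

The genetic relatedness matrix (GRM) uses the per-SNP standardized
estimator ``A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / v_i`` with
``v_i = 2 p_i (1 - p_i)`` for outbred samples and ``v_i = 4 p_i (1 - p_i)``
for fully inbred lines (whose {0,2} dosages carry twice the binomial
variance; without this adjustment the GRM diagonal sits near 2 and the
variance-component scale — hence the heritability — is off by a factor
of two).

Heritability is estimated under the single-component model
``y ~ N(X b, Vg A + Ve I)`` by restricted maximum likelihood: EM-REML
steps to warm-start, then average-information (AI) REML updates, with an
eigendecomposition of A so every iteration costs O(n).  The reported
heritability is Vg / (Vg + Ve) with a delta-method standard error from
the inverse AI matrix, and the test against Vg = 0 uses the boundary
50:50 chi0/chi1 mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .errors import DegenerateInputError, EmptyPanelError, InsufficientDataError
from .panel import GenotypePanel


@dataclass
class Grm:
    line_ids: list[str]
    matrix: np.ndarray
    n_snps_used: int

    def eigendecomposition(self):
        """Cached eigendecomposition of the full matrix (d, U).

        One GRM typically serves many trait fits; the O(n^3) factorization
        is paid once and reused whenever no lines are dropped.
        """
        if not hasattr(self, "_eig") or self._eig is None:
            d, U = np.linalg.eigh(self.matrix)
            self._eig = (np.clip(d, 0.0, None), U)
        return self._eig

    def __post_init__(self) -> None:
        self._eig = None
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over line_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if self.n_snps_used < 1:
            raise ValueError("n_snps_used must be >= 1")


@dataclass
class GremlResult:
    vg: float
    ve: float
    heritability: float
    se_heritability: float
    log_likelihood: float
    null_log_likelihood: float
    lrt: float
    p_value: float
    n_lines: int
    n_snps: int
    n_iter: int
    converged: bool
    boundary: bool

    @property
    def vp(self) -> float:
        return self.vg + self.ve


def filter_maf(panel: GenotypePanel, maf_threshold: float = 0.01) -> GenotypePanel:
    """Drop SNPs with minor allele frequency <= threshold (exclusive keep).

    Frequencies are computed on non-missing calls.  A SNP at exactly the
    threshold is removed, matching the usual command-line ``--maf``
    semantics of keeping MAF strictly above the cutoff.
    """
    if panel.n_snps == 0:
        raise EmptyPanelError("panel has no SNPs")
    maf = panel.minor_allele_freqs()
    keep = np.isfinite(maf) & (maf > maf_threshold)
    if not keep.any():
        raise EmptyPanelError(
            f"no SNPs remain at MAF > {maf_threshold}"
        )
    return GenotypePanel(
        line_ids=panel.line_ids,
        snps=panel.snps.loc[keep].copy(),
        dosages=panel.dosages[:, keep].copy(),
        inbred=panel.inbred,
        metadata=dict(panel.metadata),
    )


def build_grm(panel: GenotypePanel, inbred: bool | None = None) -> Grm:
    """Per-SNP standardized genetic relatedness matrix.

    Missing dosages are mean-imputed per SNP (to 2p) before
    standardization.  ``inbred=None`` follows the panel's own flag; pass
    False to force the outbred 2p(1-p) scaling regardless.

    Raises on monomorphic SNPs — filter them out first (:func:`filter_maf`).
    """
    if panel.n_lines < 2 or panel.n_snps < 1:
        raise InsufficientDataError("need >= 2 lines and >= 1 SNP")
    if inbred is None:
        inbred = panel.inbred
    p = panel.allele_freqs()
    if np.any(~np.isfinite(p)) or np.any((p <= 0.0) | (p >= 1.0)):
        raise DegenerateInputError(
            "monomorphic or all-missing SNP in GRM construction; apply filter_maf first"
        )
    X = panel.dosages.copy()
    mask = ~np.isfinite(X)
    if mask.any():
        X[mask] = np.broadcast_to(2.0 * p, X.shape)[mask]
    denom = 2.0 * p * (1.0 - p)
    if inbred:
        denom = 2.0 * denom
    W = (X - 2.0 * p) / np.sqrt(denom)
    m = panel.n_snps
    A = (W @ W.T) / m
    A = (A + A.T) / 2.0  # enforce exact symmetry
    return Grm(line_ids=list(panel.line_ids), matrix=A, n_snps_used=m)


# ---------------------------------------------------------------------------
# REML machinery (eigendecomposition form)
# ---------------------------------------------------------------------------

def _reml_pieces(d, yt, Xt, vg, ve):
    """logL and quadratic forms for V = vg*diag(d) + ve*I in rotated space."""
    w = 1.0 / (vg * d + ve)
    XtW = Xt * w[:, None]
    XtVX = Xt.T @ XtW  # p x p
    XtVy = XtW.T @ yt
    beta = np.linalg.solve(XtVX, XtVy)
    r = yt - Xt @ beta
    ypy = float(np.sum(w * yt * r))
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    logl = -0.5 * (np.sum(np.log(vg * d + ve)) + logdet_xvx + ypy)
    return logl, w, beta, r, XtVX


def _apply_p(z, w, Xt, XtVX):
    """P z in rotated coordinates: V^-1 z - V^-1 X (X'V^-1X)^-1 X'V^-1 z."""
    wz = w * z
    t = np.linalg.solve(XtVX, Xt.T @ wz)
    return wz - w * (Xt @ t)


def _trace_pa(d_vec, w, Xt, XtVX):
    """tr(P diag(d_vec)) for a diagonal (rotated) covariance derivative."""
    t1 = float(np.sum(w * d_vec))
    B = Xt * (w * w * d_vec)[:, None]
    M = Xt.T @ B
    t2 = float(np.trace(np.linalg.solve(XtVX, M)))
    return t1 - t2


def greml_fit(
    grm: Grm,
    phenotype,
    max_iter: int = 100,
    tol: float = 1e-8,
    n_em_warmup: int = 3,
) -> GremlResult:
    """Single-component GREML: REML estimates of (Vg, Ve) and h2 = Vg/Vp.

    ``phenotype`` is a per-line vector aligned with ``grm.line_ids`` (a
    pandas Series indexed by line id, or a plain array); lines with
    missing phenotype are dropped from both.  Convergence is declared
    when the REML log-likelihood changes by less than ``tol``; variance
    components are constrained to be nonnegative, and solutions pinned at
    the boundary are flagged.
    """
    import pandas as pd

    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(grm.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if y.shape[0] != len(grm.line_ids):
            raise ValueError("phenotype length must match GRM line count")
    keep = np.isfinite(y)
    y = y[keep]
    A = grm.matrix[np.ix_(keep, keep)]
    n = y.size
    if n < 10:
        raise InsufficientDataError("need >= 10 lines with phenotype and GRM entries")
    if y.var(ddof=1) <= 0:
        raise DegenerateInputError("phenotype variance is zero")

    if keep.all():
        d, U = grm.eigendecomposition()
    else:
        d, U = np.linalg.eigh(A)
        d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ np.ones((n, 1))
    ones_d = np.ones(n)

    vp = y.var(ddof=1)
    floor = 1e-8 * vp
    vg, ve = vp / 2.0, vp / 2.0
    logl, w, beta, r, XtVX = _reml_pieces(d, yt, Xt, vg, ve)
    n_iter = 0
    converged = False
    ai = None
    for it in range(max_iter):
        n_iter = it + 1
        py = _apply_p(yt, w, Xt, XtVX)
        apy = d * py
        papy = _apply_p(apy, w, Xt, XtVX)
        ppy = _apply_p(py, w, Xt, XtVX)
        ytpapy = float(yt @ papy)  # y'PAPy
        ytppy = float(yt @ ppy)  # y'PPy
        tr_pa = _trace_pa(d, w, Xt, XtVX)
        tr_p = _trace_pa(ones_d, w, Xt, XtVX)
        score = 0.5 * np.array([ytpapy - tr_pa, ytppy - tr_p])

        use_em = it < n_em_warmup
        if not use_em:
            papapy = _apply_p(d * papy, w, Xt, XtVX)
            pappy = _apply_p(d * ppy, w, Xt, XtVX)
            ai = 0.5 * np.array(
                [
                    [float(yt @ papapy), float(py @ (d * ppy))],
                    [float(py @ (d * ppy)), float(py @ ppy)],
                ]
            )
            # AI[0,1] should be 0.5 y'PAPPy; recompute cleanly
            ai[0, 1] = ai[1, 0] = 0.5 * float(yt @ pappy)
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                use_em = True
            else:
                if np.any(~np.isfinite(step)):
                    use_em = True
                else:
                    # damped Newton: halve an overshooting AI step (clipped
                    # steps near the Vg=0 boundary otherwise stall the fit)
                    accepted = False
                    for damp in (1.0, 0.5, 0.25, 0.125, 1 / 16, 1 / 64, 1 / 256):
                        cand = np.clip(np.array([vg, ve]) + damp * step,
                                       floor, None)
                        new_logl, *rest = _reml_pieces(d, yt, Xt, cand[0], cand[1])
                        if new_logl + 1e-12 >= logl:
                            accepted = True
                            break
                    if not accepted:
                        use_em = True
                    else:
                        vg, ve = cand
                        w, beta, r, XtVX = rest
                        if abs(new_logl - logl) < tol:
                            logl = new_logl
                            converged = True
                            break
                        logl = new_logl
        if use_em:
            vg_new = vg + vg * vg * (ytpapy - tr_pa) / n
            ve_new = ve + ve * ve * (ytppy - tr_p) / n
            vg, ve = float(np.clip(vg_new, floor, None)), float(np.clip(ve_new, floor, None))
            new_logl, w, beta, r, XtVX = _reml_pieces(d, yt, Xt, vg, ve)
            if abs(new_logl - logl) < tol:
                logl = new_logl
                converged = True
                break
            logl = new_logl

    boundary = bool(vg <= floor * 1.001 or ve <= floor * 1.001)
    vp_hat = vg + ve
    h2 = vg / vp_hat

    # SE of h2 by the delta method from the AI (expected-information proxy)
    if ai is None or not np.all(np.isfinite(ai)):
        py = _apply_p(yt, w, Xt, XtVX)
        apy = d * py
        papy = _apply_p(apy, w, Xt, XtVX)
        ppy = _apply_p(py, w, Xt, XtVX)
        pappy = _apply_p(d * ppy, w, Xt, XtVX)
        papapy = _apply_p(d * papy, w, Xt, XtVX)
        ai = 0.5 * np.array(
            [
                [float(yt @ papapy), float(yt @ pappy)],
                [float(yt @ pappy), float(py @ ppy)],
            ]
        )
    try:
        cov = np.linalg.inv(ai)
        grad = np.array([ve, -vg]) / (vp_hat**2)
        var_h2 = float(grad @ cov @ grad)
        se_h2 = math.sqrt(var_h2) if var_h2 > 0 else float("nan")
    except np.linalg.LinAlgError:
        se_h2 = float("nan")

    # null model: Vg = 0 (iid residuals), REML closed form on the same scale
    X = np.ones((n, 1))
    beta0 = y.mean()
    rss = float(np.sum((y - beta0) ** 2))
    ve0 = rss / (n - 1)
    logl0 = -0.5 * ((n - 1) * math.log(ve0) + math.log(n) + (n - 1))
    lrt = max(0.0, 2.0 * (logl - logl0))
    p = 1.0 if lrt <= 0 else 0.5 * float(st.chi2.sf(lrt, df=1))

    return GremlResult(
        vg=float(vg),
        ve=float(ve),
        heritability=float(h2),
        se_heritability=float(se_h2),
        log_likelihood=float(logl),
        null_log_likelihood=float(logl0),
        lrt=float(lrt),
        p_value=float(p),
        n_lines=n,
        n_snps=grm.n_snps_used,
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
    )


def greml_on_snp_subset(
    panel: GenotypePanel,
    snp_ids,
    phenotype,
    maf_threshold: float | None = None,
    **fit_kwargs,
) -> GremlResult:
    """GREML with the relatedness matrix rebuilt from the named SNPs only.

    The workflow for estimating how much variance a set of significant
    SNPs captures: extract the subset, (optionally) re-apply the MAF
    filter, rebuild the GRM, and rerun the REML fit.  With ``snp_ids``
    equal to the full panel the result is identical to the genome-wide
    fit.
    """
    sub = panel.subset_snps(snp_ids)
    if maf_threshold is not None:
        sub = filter_maf(sub, maf_threshold)
    grm = build_grm(sub)
    return greml_fit(grm, phenotype, **fit_kwargs)


def screen_heritable_traits(results: dict[str, GremlResult], alpha: float = 0.05) -> list[str]:
    """Traits whose GREML likelihood-ratio P falls strictly below alpha."""
    if not results:
        raise ValueError("no GREML results supplied")
    return [t for t, r in results.items() if r.p_value < alpha]
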