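"""Phylogenetic generalized least squares with Pagel's λ estimated by ML.

Shared backend for the relative-bill-size residual regression and for the
conformance-intensity regressions.  The residual covariance is
σ² · V(λ), where V(λ) multiplies the off-diagonal entries of the phylogenetic
covariance by λ ∈ [0, 1].  λ is profiled out by maximum likelihood on a
coarse grid followed by bounded 1-D refinement (tolerance 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo import PhyloCovariance, pagel_lambda_transform

__all__ = ["PglsFit", "pgls_fit"]


@dataclass
class PglsFit:
    params: np.ndarray          # GLS coefficients
    bse: np.ndarray             # standard errors
    lam: float                  # ML estimate of Pagel's λ
    resid: np.ndarray           # response-scale residuals y − Xβ
    sigma2: float               # ML residual variance (per unit V)
    loglik: float
    names: list[str]


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimate and profile log-likelihood for fixed V (ML σ²)."""
    n, p = X.shape
    L = np.linalg.cholesky(V)
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    r = ys - Xs @ beta
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, ll, XtX, y - X @ beta


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    vcv: PhyloCovariance | np.ndarray,
    lam: float | None = None,
    names: list[str] | None = None,
) -> PglsFit:
    """Fit y = Xβ + ε, ε ~ N(0, σ²·V(λ)); λ by ML unless given.

    ``X`` must include an intercept column if one is wanted.  Raises on a
    singular design.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular design matrix")
    base = vcv if isinstance(vcv, PhyloCovariance) else PhyloCovariance(
        [str(i) for i in range(len(y))], np.asarray(vcv, dtype=float)
    )
    if base.matrix.shape[0] != n:
        raise ValueError("covariance dimension does not match data")

    def ll_at(l: float) -> float:
        V = pagel_lambda_transform(base, l).matrix
        return _gls_profile(y, X, V)[2]

    if lam is None:
        grid = np.linspace(0.0, 1.0, 21)
        lls = [ll_at(l) for l in grid]
        k = int(np.argmax(lls))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi - lo < 1e-12:
            lam_hat = grid[k]
        else:
            res = minimize_scalar(
                lambda l: -ll_at(l), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4},
            )
            lam_hat = float(res.x)
            if ll_at(grid[k]) > ll_at(lam_hat):
                lam_hat = float(grid[k])
    else:
        lam_hat = float(lam)

    V = pagel_lambda_transform(base, lam_hat).matrix
    beta, sigma2, ll, XtX, resid = _gls_profile(y, X, V)
    # unbiased variance for standard errors
    dof = max(n - p, 1)
    s2_unbiased = sigma2 * n / dof
    bse = np.sqrt(np.diag(s2_unbiased * np.linalg.inv(XtX)))
    return PglsFit(
        params=beta,
        bse=bse,
        lam=lam_hat,
        resid=resid,
        sigma2=sigma2,
        loglik=ll,
        names=names or [f"x{j}" for j in range(p)],
    )
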