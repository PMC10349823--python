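"""Bill-size composites and the bill-specialization (shape rarity) score.

Four linear bill measurements (exposed culmen EC, tip-to-nares distance TND,
bill width BW, bill depth BD) are Box-Cox transformed per variable and reduced
to a single size axis: the first unrotated principal component of their
correlation matrix, with the sign convention that all PC1 loadings are
positive.  A phylogenetic PCA variant (Brownian evolutionary correlation via
GLS-centred cross-products weighted by Ω⁻¹) is provided as a robustness
check, and centroid size offers an independent landmark-based size measure.

Relative bill size is the residual of the size axis after a phylogenetic
quadratic regression on ln body mass.  Bill specialization is the rarity of a
species' position in the PC1–PC2 morphospace, quantified as a 2-D Gaussian
product-kernel density with normal-reference (Scott) bandwidths evaluated
exactly at each species' coordinates; family specialization is the mean
density over a family's sampled species (low density = rare shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgls import pgls_fit
from .phylo import PhyloCovariance

__all__ = [
    "BILL_COLUMNS",
    "PcaResult",
    "boxcox_mle",
    "boxcox_transform",
    "bill_size_pc1",
    "phylo_pca_pc1",
    "centroid_size",
    "relative_bill_size",
    "kde2d_density",
    "specialization_scores",
]

BILL_COLUMNS = ["ec_mm", "tnd_mm", "bw_mm", "bd_mm"]


@dataclass
class PcaResult:
    loadings: pd.DataFrame          # variables × components, orthonormal eigenvectors
    scores: pd.DataFrame            # observations × components
    variance_explained: np.ndarray  # fraction per component
    boxcox_lambdas: dict | None = None

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


# ---------------------------------------------------------------------------
# Box-Cox


def _boxcox_loglik(x: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of the Box-Cox model at λ (σ² profiled out)."""
    n = len(x)
    z = boxcox_transform(x, lam)
    var = z.var()
    if var <= 0:
        return -np.inf
    return -0.5 * n * np.log(var) + (lam - 1.0) * np.log(x).sum()


def boxcox_mle(x, lower: float = -5.0, upper: float = 5.0, tol: float = 1e-6) -> float:
    """MLE of the Box-Cox exponent by golden-section search on [lower, upper]."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant data: Box-Cox likelihood undefined")

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lower, upper
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = _boxcox_loglik(x, c), _boxcox_loglik(x, d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _boxcox_loglik(x, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _boxcox_loglik(x, d)
    return 0.5 * (a + b)


def boxcox_transform(x, lam: float) -> np.ndarray:
    """(x^λ − 1)/λ, or ln x in the |λ| < 1e-8 limit."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if abs(lam) < 1e-8:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


# ---------------------------------------------------------------------------
# PCA composites


def _fix_pc_signs(eigvecs: np.ndarray) -> np.ndarray:
    """Flip each component so its loading sum is positive (all-positive PC1)."""
    signs = np.sign(eigvecs.sum(axis=0))
    signs[signs == 0] = 1.0
    return eigvecs * signs


def bill_size_pc1(
    measurements: pd.DataFrame,
    columns: list[str] | None = None,
    apply_boxcox: bool = True,
) -> PcaResult:
    """Correlation-based PCA of the (Box-Cox transformed) bill measurements."""
    columns = columns or [c for c in BILL_COLUMNS if c in measurements.columns]
    data = measurements[columns].to_numpy(dtype=float)
    if data.shape[0] < 5:
        raise ValueError("need at least 5 species for the PCA")
    if np.any(data <= 0) and apply_boxcox:
        raise ValueError("bill measurements must be strictly positive")
    lambdas = None
    if apply_boxcox:
        lambdas = {c: boxcox_mle(data[:, j]) for j, c in enumerate(columns)}
        data = np.column_stack(
            [boxcox_transform(data[:, j], lambdas[c]) for j, c in enumerate(columns)]
        )
    sd = data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant measurement column")
    z = (data - data.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    if np.linalg.matrix_rank(corr) < corr.shape[0]:
        import warnings

        warnings.warn("rank-deficient correlation matrix; proceeding", stacklevel=2)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], _fix_pc_signs(eigvecs[:, order])
    comp_names = [f"PC{j + 1}" for j in range(len(columns))]
    scores = z @ eigvecs
    return PcaResult(
        loadings=pd.DataFrame(eigvecs, index=columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=measurements.index, columns=comp_names),
        variance_explained=np.clip(eigvals, 0, None) / len(columns),
        boxcox_lambdas=lambdas,
    )


def phylo_pca_pc1(
    measurements: pd.DataFrame,
    vcv: PhyloCovariance,
    columns: list[str] | None = None,
    apply_boxcox: bool = True,
) -> PcaResult:
    """PCA of the Brownian evolutionary correlation matrix.

    Rows of ``measurements`` must be indexed by the taxa in ``vcv`` (any
    order); a label mismatch is an error.  The evolutionary covariance is
    (X − 1â')' Ω⁻¹ (X − 1â') / (n − 1) with â the GLS phylogenetic mean; on a
    star phylogeny this reduces exactly to ordinary PCA.
    """
    labels = list(measurements.index)
    if set(labels) != set(vcv.labels) or len(labels) != len(vcv.labels):
        raise KeyError("measurement index does not match covariance labels")
    omega = vcv.reorder(labels).matrix
    columns = columns or [c for c in BILL_COLUMNS if c in measurements.columns]
    data = measurements[columns].to_numpy(dtype=float)
    if apply_boxcox:
        data = np.column_stack(
            [boxcox_transform(data[:, j], boxcox_mle(data[:, j])) for j in range(data.shape[1])]
        )
    n = data.shape[0]
    oinv = np.linalg.inv(omega)
    ones = np.ones(n)
    anc = (ones @ oinv @ data) / (ones @ oinv @ ones)  # GLS phylogenetic mean
    centred = data - anc
    cov = centred.T @ oinv @ centred / (n - 1)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], _fix_pc_signs(eigvecs[:, order])
    comp_names = [f"PC{j + 1}" for j in range(len(columns))]
    scores = (centred / d) @ eigvecs
    return PcaResult(
        loadings=pd.DataFrame(eigvecs, index=columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=measurements.index, columns=comp_names),
        variance_explained=np.clip(eigvals, 0, None) / len(columns),
    )


# ---------------------------------------------------------------------------
# Landmarks


def centroid_size(config: np.ndarray, expected_landmarks: int | None = 79) -> float:
    """Square root of summed squared landmark distances to their centroid.

    ``config`` is a (k, d) array of landmark coordinates.  The conventional
    ingest expects k = 79 3-D landmarks; pass ``expected_landmarks=None`` to
    accept any configuration size.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2:
        raise ValueError("landmark configuration must be a 2-D array")
    if not np.all(np.isfinite(config)):
        raise ValueError("landmark coordinates must be finite")
    if expected_landmarks is not None and config.shape[0] != expected_landmarks:
        raise ValueError(
            f"expected {expected_landmarks} landmarks, got {config.shape[0]}"
        )
    centred = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


# ---------------------------------------------------------------------------
# Relative bill size


def relative_bill_size(
    bill_pc1: np.ndarray,
    ln_mass: np.ndarray,
    vcv: PhyloCovariance | np.ndarray,
    lam: float | None = None,
) -> np.ndarray:
    """Residuals of a phylogenetic quadratic regression of bill size on ln mass.

    Fits bill ~ 1 + ln mass + ln mass² by GLS under Pagel-λ-scaled Ω (λ by ML
    unless fixed) and returns the response-scale residuals; invariant to
    adding a constant to ``bill_pc1``.
    """
    bill_pc1 = np.asarray(bill_pc1, dtype=float)
    ln_mass = np.asarray(ln_mass, dtype=float)
    X = np.column_stack([np.ones_like(ln_mass), ln_mass, ln_mass**2])
    fit = pgls_fit(bill_pc1, X, vcv, lam=lam, names=["const", "ln_mass", "ln_mass_sq"])
    return fit.resid


# ---------------------------------------------------------------------------
# Specialization (2-D kernel density)


def _scott_bandwidths(points: np.ndarray) -> np.ndarray:
    """Normal-reference (Scott) per-axis bandwidths for a 2-D product kernel."""
    n, d = points.shape
    return points.std(axis=0, ddof=1) * n ** (-1.0 / (d + 4))


def kde2d_density(points: np.ndarray, eval_at: np.ndarray | None = None) -> np.ndarray:
    """Gaussian product-kernel density with Scott bandwidths.

    Evaluated exactly at ``eval_at`` (default: at the sample points
    themselves, self-contribution included, as in standard KDE evaluation).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = points.shape[0]
    if n < 20:
        raise ValueError("need at least 20 points for a stable bandwidth")
    h = _scott_bandwidths(points)
    if np.any(h <= 0):
        raise ValueError("degenerate (zero-variance) morphospace axis")
    where = points if eval_at is None else np.asarray(eval_at, dtype=float)
    u = (where[:, None, :] - points[None, :, :]) / h  # (m, n, 2)
    kern = np.exp(-0.5 * np.sum(u**2, axis=2)) / (2 * np.pi * h.prod())
    return kern.sum(axis=1) / n


def specialization_scores(
    pc_points: pd.DataFrame, family_labels: pd.Series | np.ndarray
) -> tuple[pd.Series, pd.Series]:
    """Per-species kernel density and per-family mean density in morphospace.

    ``pc_points`` must have two columns (PC1, PC2).  Returns
    ``(species_density, family_mean_density)``; low values mark rare
    (specialized) bill shapes.
    """
    pts = pc_points.to_numpy(dtype=float)
    dens = kde2d_density(pts)
    species_density = pd.Series(dens, index=pc_points.index, name="kernel_density")
    fams = pd.Series(np.asarray(family_labels), index=pc_points.index, name="family")
    family_mean = species_density.groupby(fams).mean()
    family_mean.name = "mean_kernel_density"
    return species_density, family_mean
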