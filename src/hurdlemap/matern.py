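"""Matérn covariance functions and Gaussian-field sampling over tract centroids.

The spatial random effect S is a zero-mean Gaussian field with stationary
Matérn covariance

    C(d) = sigma2 / (2**(nu-1) * Gamma(nu)) * (kappa*d)**nu * K_nu(kappa*d)

where ``K_nu`` is the modified Bessel function of the second kind. The range
``rho = sqrt(8*nu)/kappa`` is the distance at which the correlation has fallen
to roughly 0.1. Coordinates must be in a projected, metre-based system;
distances are Euclidean.

The field is evaluated exactly at tract centroids (dense covariance matrix plus
Cholesky factorisation) rather than through a mesh/SPDE approximation: exact
and fast at the scale of a few hundred tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln, kv


@dataclass(frozen=True)
class MaternParams:
    """Hyperparameters of the Matérn family.

    Attributes
    ----------
    sigma2 : float
        Marginal variance (> 0).
    nu : float
        Smoothness (> 0). Defaults to 1, the conventional SPDE default.
    kappa : float
        Inverse-scale parameter (> 0), units 1/metre.
    """

    sigma2: float
    nu: float
    kappa: float

    def __post_init__(self) -> None:
        for name in ("sigma2", "nu", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"MaternParams.{name} must be strictly positive, got {v!r}")

    @property
    def rho(self) -> float:
        """Spatial range sqrt(8*nu)/kappa: distance where correlation ~ 0.1."""
        return range_from_kappa(self.nu, self.kappa)


def range_from_kappa(nu: float, kappa: float) -> float:
    """Return the Matérn range ``rho = sqrt(8*nu)/kappa``."""
    if nu <= 0 or kappa <= 0:
        raise ValueError(f"nu and kappa must be positive, got nu={nu}, kappa={kappa}")
    return float(np.sqrt(8.0 * nu) / kappa)


def kappa_from_range(nu: float, rho: float) -> float:
    """Inverse of :func:`range_from_kappa`."""
    if nu <= 0 or rho <= 0:
        raise ValueError(f"nu and rho must be positive, got nu={nu}, rho={rho}")
    return float(np.sqrt(8.0 * nu) / rho)


def matern_covariance(distance, params: MaternParams):
    """Evaluate the Matérn covariance at one or more distances.

    Returns ``sigma2`` exactly at distance 0 (the limit value). Vectorised over
    ``distance``; scalars in, scalar out.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.full(d.shape, params.sigma2, dtype=float)
    pos = d > 0
    if np.any(pos):
        u = params.kappa * d[pos]
        # log-space for the prefactor; kv itself underflows gracefully to 0
        log_pref = np.log(params.sigma2) - (params.nu - 1.0) * np.log(2.0) - gammaln(params.nu)
        bess = kv(params.nu, u)
        with np.errstate(divide="ignore"):
            val = np.where(
                bess > 0,
                np.exp(log_pref + params.nu * np.log(u) + np.log(bess)),
                0.0,
            )
        out[pos] = val
    return float(out[0]) if scalar else out


def covariance_matrix(
    centroids: np.ndarray,
    params: MaternParams,
    jitter: float | None = None,
) -> np.ndarray:
    """Dense Matérn covariance matrix over centroids, with diagonal jitter.

    The default jitter is ``1e-8 * sigma2``. If Cholesky factorisation fails the
    jitter is escalated by a factor of 10 up to three times before a numerical
    error is raised.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("centroids must be a non-empty (n, 2) array")
    if jitter is None:
        jitter = 1e-8 * params.sigma2
    dist = cdist(pts, pts)
    cov = matern_covariance(dist.ravel(), params).reshape(dist.shape)
    np.fill_diagonal(cov, params.sigma2)
    cov = 0.5 * (cov + cov.T)
    cov[np.diag_indices_from(cov)] += jitter
    return cov


def cholesky_with_jitter(cov: np.ndarray, sigma2: float) -> np.ndarray:
    """Lower Cholesky factor of ``cov``, escalating diagonal jitter on failure."""
    extra = 0.0
    step = 1e-8 * sigma2
    for attempt in range(4):
        try:
            return np.linalg.cholesky(cov + extra * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            extra = step * 10.0 ** (attempt + 1)
    raise np.linalg.LinAlgError(
        "Matérn covariance matrix is not positive definite even after jitter "
        f"escalation to {extra:g}; check for (near-)duplicate centroids or an "
        "extreme range/smoothness combination."
    )


def correlation_cholesky(
    centroids: np.ndarray, nu: float, kappa: float, jitter: float = 1e-8
) -> np.ndarray:
    """Cholesky factor of the Matérn *correlation* matrix (sigma2 = 1)."""
    params = MaternParams(sigma2=1.0, nu=nu, kappa=kappa)
    cov = covariance_matrix(centroids, params, jitter=jitter)
    return cholesky_with_jitter(cov, 1.0)


def sample_field(
    centroids: np.ndarray,
    params: MaternParams,
    seed: int | np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw zero-mean Gaussian field realisation(s) at the centroids.

    Parameters
    ----------
    seed : int or Generator
        Randomness source; an int seeds a fresh :class:`numpy.random.Generator`.
    size : int, optional
        Number of independent realisations; default a single draw of shape (n,).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = covariance_matrix(centroids, params)
    chol = cholesky_with_jitter(cov, params.sigma2)
    n = chol.shape[0]
    if size is None:
        return chol @ rng.standard_normal(n)
    return (chol @ rng.standard_normal((n, size))).T
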