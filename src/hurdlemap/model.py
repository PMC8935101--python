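"""Two-part (hurdle) likelihood with shared spatial, temporal, and IID latents.

The observed count Y_it of police reports in tract i, period t enters two
jointly estimated likelihood parts:

* a binomial "reporting" part, Y_it ~ Binomial(n_trials_i, P_it) with
  logit(P_it) = b0 + x_i' beta_B + eta_i + S(x_i) + tau_t, where n_trials_i is
  the tract population at risk;
* a Poisson "count" part, Y_it ~ Poisson(theta_it) with
  log(theta_it) = b0' + x_i' beta_P + alpha * (eta_i + S(x_i) + tau_t).

The Poisson part is applied to all observations, not only positive counts (no
truncation). The latent effects — eta (IID tract heterogeneity), S (Matérn
Gaussian field at centroids), tau (first-order random walk over periods,
sum-to-zero) — are shared between the parts, with a scaling factor
``alpha_share`` (default 1) on the Poisson side. Fixed-effect vectors are
separate per part, which nests the shared-coefficient case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .matern import MaternParams, cholesky_with_jitter, covariance_matrix

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LatentEffects:
    """Realisations (or one posterior draw) of the three latent components."""

    eta: np.ndarray  # per-tract IID heterogeneity
    tau: np.ndarray  # per-period RW1, sum-to-zero
    S: np.ndarray  # per-tract spatial field

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.eta.shape != self.S.shape:
            raise ValueError("eta and S must have one value per tract each")
        if self.tau.size and abs(self.tau.sum()) > 1e-10 * max(1.0, np.abs(self.tau).max()):
            raise ValueError("tau must satisfy the sum-to-zero constraint")

    @classmethod
    def zeros(cls, n_tracts: int, n_periods: int) -> "LatentEffects":
        return cls(np.zeros(n_tracts), np.zeros(n_periods), np.zeros(n_tracts))


@dataclass
class ModelParameters:
    """Fixed effects and hyperparameters of the two-part model.

    ``beta_binomial`` / ``beta_poisson`` are arrays of length p+1 whose first
    entry is the intercept; exp(beta) is the odds/rate ratio reported for each
    covariate term.
    """

    beta_binomial: np.ndarray
    beta_poisson: np.ndarray
    matern: MaternParams
    var_eta: float = 0.0
    var_tau: float = 0.0
    alpha_share: float = 1.0

    def __post_init__(self) -> None:
        self.beta_binomial = np.asarray(self.beta_binomial, dtype=float)
        self.beta_poisson = np.asarray(self.beta_poisson, dtype=float)
        if self.beta_binomial.shape != self.beta_poisson.shape:
            raise ValueError("the two coefficient vectors must have the same length")
        if self.var_eta < 0 or self.var_tau < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class PanelDataset:
    """Unbalanced tract x period panel of report counts plus model inputs.

    Attributes
    ----------
    obs : DataFrame
        Columns ``tract_id``, ``period``, ``count``; one row per observed
        tract-period (the panel may be unbalanced).
    n_trials : Series
        Population at risk per tract, indexed by tract_id.
    design : DataFrame
        Tract-level fixed-effects design matrix (index tract_id).
    centroids : ndarray, shape (n, 2)
        Projected tract centroid coordinates in metres, ordered as ``design``.
    truth : dict, optional
        Generative ground truth attached by the simulator (latents, gates,
        coefficient vectors) for recovery tests.
    """

    obs: pd.DataFrame
    n_trials: pd.Series
    design: pd.DataFrame
    centroids: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"tract_id", "period", "count"}
        if not req.issubset(self.obs.columns):
            raise ValueError(f"obs must have columns {sorted(req)}")
        self.centroids = np.asarray(self.centroids, dtype=float)
        tract_ids = list(self.design.index)
        if self.centroids.shape != (len(tract_ids), 2):
            raise ValueError("centroids must be (n_tracts, 2) aligned with the design index")
        unknown = set(self.obs["tract_id"]) - set(tract_ids)
        if unknown:
            raise ValueError(f"obs reference tract ids absent from the design: {sorted(unknown)[:5]}")
        if (self.obs["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        trials = self.n_trials.loc[self.obs["tract_id"]].to_numpy()
        if (self.obs["count"].to_numpy() > trials).any():
            raise ValueError("a count exceeds its tract population at risk")
        self._tract_pos = {tid: k for k, tid in enumerate(tract_ids)}
        if len(self.obs):
            periods = np.sort(self.obs["period"].unique())
            if not np.array_equal(periods, np.arange(periods.min(), periods.max() + 1)):
                raise ValueError("period labels must be contiguous integers")
            self._period0 = int(periods.min())
            self.n_periods = int(periods.max() - periods.min() + 1)
        else:
            self._period0 = 1
            self.n_periods = 1

    @property
    def n_tracts(self) -> int:
        return len(self.design)

    @property
    def tract_index(self) -> np.ndarray:
        """0-based tract position per observation row."""
        return self.obs["tract_id"].map(self._tract_pos).to_numpy()

    @property
    def period_index(self) -> np.ndarray:
        """0-based period position per observation row."""
        return (self.obs["period"] - self._period0).to_numpy()

    @property
    def counts(self) -> np.ndarray:
        return self.obs["count"].to_numpy(dtype=float)

    @property
    def trials(self) -> np.ndarray:
        """Population at risk per observation row."""
        return self.n_trials.loc[self.obs["tract_id"]].to_numpy(dtype=float)

    def design_array(self) -> np.ndarray:
        return self.design.to_numpy(dtype=float)


def linear_predictor(x, beta, latents: LatentEffects, i: int, t: int, alpha: float = 1.0) -> float:
    """Single-observation linear predictor b0 + x'beta + alpha*(eta_i + S_i + tau_t).

    ``beta`` carries the intercept in its first entry; ``i`` and ``t`` are
    0-based tract and period positions.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.size != beta.size - 1:
        raise ValueError("design row and coefficient vector are not conformable")
    if not (0 <= i < latents.eta.size) or not (0 <= t < latents.tau.size):
        raise IndexError("tract or period index out of range")
    return float(
        beta[0] + x @ beta[1:] + alpha * (latents.eta[i] + latents.S[i] + latents.tau[t])
    )


def linear_predictors(panel: PanelDataset, beta, latents: LatentEffects, alpha: float = 1.0):
    """Vectorised linear predictors for every observation row."""
    X = panel.design_array()
    u = latents.eta + latents.S
    ti, pi = panel.tract_index, panel.period_index
    beta = np.asarray(beta, dtype=float)
    return beta[0] + X[ti] @ beta[1:] + alpha * (u[ti] + latents.tau[pi])


def _softplus(x):
    return np.logaddexp(0.0, x)


def binomial_loglik(count, n_trials, predictor):
    """Log binomial pmf at p = logistic(predictor), stable for |predictor| up to ~700."""
    y = np.asarray(count, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    ell = np.asarray(predictor, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("count must satisfy 0 <= count <= n_trials")
    ll = (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + y * ell - n * _softplus(ell)
    )
    return float(ll) if ll.ndim == 0 else ll


def poisson_loglik(count, predictor):
    """Log Poisson pmf with log-rate ``predictor``: y*l - exp(l) - log(y!)."""
    y = np.asarray(count, dtype=float)
    ell = np.asarray(predictor, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("count must be a non-negative integer")
    ll = y * ell - np.exp(ell) - gammaln(y + 1)
    return float(ll) if ll.ndim == 0 else ll


def _gaussian_iid_logpdf(x: np.ndarray, var: float) -> float:
    """IID N(0, var) log-density; var=0 is the point mass at zero."""
    if var == 0:
        return 0.0 if np.all(x == 0) else -np.inf
    return float(-0.5 * x.size * (_LOG_2PI + np.log(var)) - 0.5 * np.sum(x**2) / var)


def rw1_logpdf(tau: np.ndarray, var: float) -> float:
    """First-order random-walk log-density: IID Gaussian increments.

    The sum-to-zero constraint is imposed structurally (by construction of tau),
    so the density is evaluated on the T-1 increments only.
    """
    if tau.size <= 1:
        return 0.0
    inc = np.diff(tau)
    return _gaussian_iid_logpdf(inc, var)


def spatial_logpdf(S: np.ndarray, centroids: np.ndarray, matern: MaternParams) -> float:
    """Zero-mean MVN log-density of the spatial field under the Matérn covariance."""
    cov = covariance_matrix(centroids, matern)
    chol = cholesky_with_jitter(cov, matern.sigma2)
    w = np.linalg.solve(chol, np.asarray(S, dtype=float))
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (S.size * _LOG_2PI + logdet + w @ w))


def joint_loglik(panel: PanelDataset, params: ModelParameters, latents: LatentEffects) -> float:
    """Joint log-likelihood of both parts plus the latent Gaussian log-densities.

    Sum over observations of the binomial part (binomial coefficients, shared
    latents) and the Poisson part (Poisson coefficients, shared latents scaled
    by ``alpha_share``), plus MVN(0, Matérn) for S, IID N(0, var_eta) for eta,
    and RW1(var_tau) increments for tau.
    """
    if params.beta_binomial.size != panel.design.shape[1] + 1:
        raise ValueError(
            f"coefficient vectors must have length {panel.design.shape[1] + 1} "
            f"(intercept + design columns), got {params.beta_binomial.size}"
        )
    if latents.eta.size != panel.n_tracts or latents.tau.size != panel.n_periods:
        raise ValueError("latent effect lengths do not match the panel")
    total = 0.0
    if len(panel.obs):
        ell1 = linear_predictors(panel, params.beta_binomial, latents)
        ell2 = linear_predictors(panel, params.beta_poisson, latents, alpha=params.alpha_share)
        total += float(np.sum(binomial_loglik(panel.counts, panel.trials, ell1)))
        total += float(np.sum(poisson_loglik(panel.counts, ell2)))
    total += _gaussian_iid_logpdf(latents.eta, params.var_eta)
    total += rw1_logpdf(latents.tau, params.var_tau)
    total += spatial_logpdf(latents.S, panel.centroids, params.matern)
    return total


def gate_probability(predictor):
    """Reporting probability logistic(predictor) of the binomial part."""
    return expit(predictor)
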