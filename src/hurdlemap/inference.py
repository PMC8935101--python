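"""Bayesian estimation of the two-part model by MCMC.

The posterior over fixed effects, variance/range hyperparameters, and latent
fields is the joint log-likelihood of :mod:`hurdlemap.model` plus
weakly-informative priors. Sampling combines

* Hamiltonian Monte Carlo (leapfrog integrator, dual-averaging step-size
  adaptation, diagonal mass matrix estimated during warmup) on the
  *non-centred* block — coefficients, whitened latent fields, and the log
  standard deviations of the IID/temporal/spatial components, whose gradients
  are analytic;
* adaptive random-walk Metropolis on the log Matérn range (its gradient would
  require differentiating a Cholesky factor), conditional on the whitened
  spatial field;
* interweaved rescaling moves that propose a hyperparameter change while
  holding the latent fields themselves fixed, which keeps the scales mobile
  when the data pin the latents tightly.

The non-centred parameterisation (eta = sd_eta * z, S = sd_S * L(rho) * z,
tau = sd_tau * RW1(z) with a sum-to-zero constraint) avoids the funnel
pathology when variances are small. Covariates are standardised internally
and coefficient draws mapped back to the original scale, so the reported
exp(coefficient) is the odds/rate ratio per raw covariate unit.

The Matérn smoothness nu is fixed (default 1) rather than sampled; the latent
sharing factor alpha between the two parts is fixed at its default 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit

from .matern import correlation_cholesky, kappa_from_range
from .model import PanelDataset

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "Posterior",
    "fit",
    "summarize",
    "diagnostics",
]

ALL_LATENTS = ("eta", "spatial", "temporal")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative priors; nothing in the published analysis pins them.

    ``beta_prior_sd`` applies to the intercepts and to coefficients of the
    internally standardised covariates. Half-normal priors act on the latent
    standard deviations; the spatial range gets a log-normal prior whose median
    defaults to 20% of the centroid-domain diameter.
    """

    beta_prior_sd: float = 5.0
    sd_eta_scale: float = 1.0
    sd_tau_scale: float = 1.0
    sd_s_scale: float = 1.0
    range_median: float | None = None
    range_sdlog: float = 0.7
    nu: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta_prior_sd", "sd_eta_scale", "sd_tau_scale", "sd_s_scale", "range_sdlog", "nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PriorConfig.{name} must be positive")
        if self.range_median is not None and self.range_median <= 0:
            raise ValueError("PriorConfig.range_median must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 2
    draws: int = 500
    warmup: int = 500
    max_leapfrog: int = 48
    target_accept: float = 0.9
    alpha_share: float = 1.0
    latent_components: tuple = ALL_LATENTS
    init_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 1:
            raise ValueError("chains, draws, and warmup must be positive")
        bad = set(self.latent_components) - set(ALL_LATENTS)
        if bad:
            raise ValueError(f"unknown latent component(s): {sorted(bad)}")


@dataclass
class Posterior:
    """Posterior draws keyed by parameter name, shape (chains, draws[, dim])."""

    draws: dict
    design_columns: list
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: shape (chains*draws[, dim])."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def term_names(self) -> list:
        return ["intercept"] + list(self.design_columns)

    def scalar_map(self) -> dict:
        """Every stored scalar as name -> (chains, draws) array."""
        out = {}
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                labels = self.term_names if name.startswith("beta_") else range(arr.shape[2])
                for k, lab in enumerate(labels):
                    out[f"{name}[{lab}]"] = arr[:, :, k]
        return out

    def save(self, out_dir) -> None:
        """Serialise to per-parameter CSV arrays plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        shapes = {}
        for name, arr in self.draws.items():
            flat = arr.reshape(self.n_chains * self.n_draws, -1)
            cols = (
                self.term_names
                if name.startswith("beta_")
                else [str(i) for i in range(flat.shape[1])]
            )
            pd.DataFrame(flat, columns=cols).to_csv(out / f"{name}.csv", index=False)
            shapes[name] = list(arr.shape)
        manifest = {
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "design_columns": list(self.design_columns),
            "shapes": shapes,
            "meta": _jsonable(self.meta),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, out_dir) -> "Posterior":
        out = Path(out_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        draws = {}
        for name, shape in manifest["shapes"].items():
            flat = pd.read_csv(out / f"{name}.csv").to_numpy(dtype=float)
            draws[name] = flat.reshape(shape)
        return cls(draws, manifest["design_columns"], manifest.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# posterior density


class _TargetDensity:
    """Unnormalised joint posterior with analytic gradients on the HMC block.

    HMC block q = [b0_B, beta_B_std, b0_P, beta_P_std, z_eta?, z_S?, z_tau?,
    log_sd_eta?, log_sd_tau?, log_sd_s?]; the log Matérn range is handled
    separately by Metropolis because its gradient would require Cholesky
    differentiation.
    """

    def __init__(self, panel: PanelDataset, prior: PriorConfig, cfg: SamplerConfig):
        X = panel.design_array()
        self.p = X.shape[1]
        self.n = panel.n_tracts
        self.T = panel.n_periods
        self.mu_x = X.mean(axis=0) if len(X) else np.zeros(self.p)
        sx = X.std(axis=0) if len(X) else np.ones(self.p)
        sx[sx == 0] = 1.0
        self.sx = sx
        self.Xs = (X - self.mu_x) / self.sx
        self.ti = panel.tract_index
        self.pi = panel.period_index
        self.Xo = self.Xs[self.ti] if len(panel.obs) else np.zeros((0, self.p))
        self.y = panel.counts
        self.ntr = panel.trials
        self.centroids = panel.centroids
        self.prior = prior
        self.alpha = cfg.alpha_share
        self.use_eta = "eta" in cfg.latent_components
        self.use_spatial = "spatial" in cfg.latent_components
        self.use_temporal = "temporal" in cfg.latent_components and self.T > 1

        if prior.range_median is not None:
            self.range_median = prior.range_median
        elif self.use_spatial:
            span = self.centroids.max(axis=0) - self.centroids.min(axis=0)
            self.range_median = max(0.2 * float(np.linalg.norm(span)), 1e-6)
        else:
            self.range_median = 1.0

        sizes = [self.p + 1, self.p + 1]
        names = ["bB", "bP"]
        if self.use_eta:
            sizes.append(self.n)
            names.append("z_eta")
        if self.use_spatial:
            sizes.append(self.n)
            names.append("z_S")
        if self.use_temporal:
            sizes.append(self.T - 1)
            names.append("z_tau")
        self.ls_names = []
        if self.use_eta:
            self.ls_names.append("log_sd_eta")
        if self.use_temporal:
            self.ls_names.append("log_sd_tau")
        if self.use_spatial:
            self.ls_names.append("log_sd_s")
        if self.ls_names:
            sizes.append(len(self.ls_names))
            names.append("ls")
        edges = np.concatenate([[0], np.cumsum(sizes)])
        self.slices = {nm: slice(int(a), int(b)) for nm, a, b in zip(names, edges[:-1], edges[1:])}
        self.dim_q = int(edges[-1])
        self.sample_rho = self.use_spatial

    # -- initial state

    def q_init(self) -> np.ndarray:
        q = np.zeros(self.dim_q)
        if len(self.y):
            ybar = max(float(self.y.mean()), 1e-3)
            nbar = float(self.ntr.mean())
            q[self.slices["bB"].start] = float(np.log(ybar / max(nbar - ybar, 1.0)))
            q[self.slices["bP"].start] = float(np.log(ybar))
        # start with most latent scale on the spatial component: if tract-level
        # structure is spatially correlated the chain finds the S-mode directly,
        # and if not, sigma2 shrinks during warmup; a large IID scale at the
        # start can instead trap eta in a mode that soaks up spatial signal
        init_ls = {"log_sd_eta": np.log(0.05), "log_sd_tau": np.log(0.1), "log_sd_s": np.log(0.5)}
        for k, nm in enumerate(self.ls_names):
            q[self.slices["ls"].start + k] = init_ls[nm]
        return q

    def chol_for(self, log_rho: float) -> np.ndarray | None:
        if not self.use_spatial:
            return None
        kappa = kappa_from_range(self.prior.nu, float(np.exp(log_rho)))
        return correlation_cholesky(self.centroids, self.prior.nu, kappa)

    def _sds(self, q: np.ndarray):
        out = {}
        for k, nm in enumerate(self.ls_names):
            out[nm] = float(np.exp(q[self.slices["ls"].start + k]))
        return out.get("log_sd_eta", 0.0), out.get("log_sd_tau", 0.0), out.get("log_sd_s", 0.0)

    def ls_index(self, nm: str) -> int:
        return self.slices["ls"].start + self.ls_names.index(nm)

    # -- reconstruction

    def latents(self, q: np.ndarray, L: np.ndarray | None):
        sd_eta, sd_tau, sd_s = self._sds(q)
        eta = sd_eta * q[self.slices["z_eta"]] if self.use_eta else np.zeros(self.n)
        S = sd_s * (L @ q[self.slices["z_S"]]) if self.use_spatial else np.zeros(self.n)
        if self.use_temporal:
            walk = np.concatenate([[0.0], np.cumsum(q[self.slices["z_tau"]])])
            tau = sd_tau * (walk - walk.mean())
        else:
            tau = np.zeros(self.T)
        return eta, tau, S

    def _predictors(self, q, eta, tau, S):
        bB = q[self.slices["bB"]]
        bP = q[self.slices["bP"]]
        u = (eta + S)[self.ti] + tau[self.pi]
        l1 = bB[0] + self.Xo @ bB[1:] + u
        l2 = bP[0] + self.Xo @ bP[1:] + self.alpha * u
        return l1, l2

    def loglik(self, q: np.ndarray, L: np.ndarray | None) -> float:
        """Data log-likelihood only (count-independent constants dropped)."""
        if not len(self.y):
            return 0.0
        eta, tau, S = self.latents(q, L)
        l1, l2 = self._predictors(q, eta, tau, S)
        if max(np.abs(l1).max(), np.abs(l2).max()) > 200:
            return -np.inf
        ll = np.sum(self.y * l1 - self.ntr * np.logaddexp(0.0, l1))
        ll += np.sum(self.y * l2 - np.exp(l2))
        return float(ll)

    # -- priors

    def _ls_prior_scale(self, nm: str) -> float:
        return {
            "log_sd_eta": self.prior.sd_eta_scale,
            "log_sd_tau": self.prior.sd_tau_scale,
            "log_sd_s": self.prior.sd_s_scale,
        }[nm]

    def logprior_q(self, q: np.ndarray) -> float:
        sd_b = self.prior.beta_prior_sd
        lp = -0.5 * (np.sum(q[self.slices["bB"]] ** 2) + np.sum(q[self.slices["bP"]] ** 2)) / sd_b**2
        for nm in ("z_eta", "z_S", "z_tau"):
            if nm in self.slices:
                lp += -0.5 * np.sum(q[self.slices[nm]] ** 2)
        for k, nm in enumerate(self.ls_names):
            ls = q[self.slices["ls"].start + k]
            s = self._ls_prior_scale(nm)
            # half-normal on sd plus the log-Jacobian of the log transform
            lp += -0.5 * np.exp(2 * ls) / s**2 + ls
        return float(lp)

    def logprior_rho(self, log_rho: float) -> float:
        return float(-0.5 * ((log_rho - np.log(self.range_median)) / self.prior.range_sdlog) ** 2)

    def logpost_and_grad(self, q: np.ndarray, L: np.ndarray | None):
        """Posterior density (rho prior excluded) and gradient w.r.t. q."""
        sd_eta, sd_tau, sd_s = self._sds(q)
        eta, tau, S = self.latents(q, L)
        grad = np.zeros_like(q)
        sd_b2 = self.prior.beta_prior_sd**2
        if len(self.y):
            l1, l2 = self._predictors(q, eta, tau, S)
            if max(np.abs(l1).max(), np.abs(l2).max()) > 200:
                return -np.inf, grad
            rate2 = np.exp(l2)
            ll = float(np.sum(self.y * l1 - self.ntr * np.logaddexp(0.0, l1)))
            ll += float(np.sum(self.y * l2 - rate2))
            g1 = self.y - self.ntr * expit(l1)
            g2 = self.y - rate2
        else:
            ll = 0.0
            g1 = g2 = np.zeros(0)

        grad[self.slices["bB"]] = (
            np.concatenate([[g1.sum()], self.Xo.T @ g1]) - q[self.slices["bB"]] / sd_b2
        )
        grad[self.slices["bP"]] = (
            np.concatenate([[g2.sum()], self.Xo.T @ g2]) - q[self.slices["bP"]] / sd_b2
        )

        h = g1 + self.alpha * g2
        h_tract = np.bincount(self.ti, weights=h, minlength=self.n) if len(h) else np.zeros(self.n)
        if self.use_eta:
            grad[self.slices["z_eta"]] = sd_eta * h_tract - q[self.slices["z_eta"]]
            grad[self.ls_index("log_sd_eta")] = float(eta @ h_tract)
        if self.use_spatial:
            grad[self.slices["z_S"]] = sd_s * (L.T @ h_tract) - q[self.slices["z_S"]]
            grad[self.ls_index("log_sd_s")] = float(S @ h_tract)
        if self.use_temporal:
            h_per = np.bincount(self.pi, weights=h, minlength=self.T) if len(h) else np.zeros(self.T)
            c = h_per - h_per.mean()
            rc = np.cumsum(c[::-1])[::-1]
            grad[self.slices["z_tau"]] = sd_tau * rc[1:] - q[self.slices["z_tau"]]
            grad[self.ls_index("log_sd_tau")] = float(tau @ h_per)
        for k, nm in enumerate(self.ls_names):
            j = self.slices["ls"].start + k
            s = self._ls_prior_scale(nm)
            grad[j] += -np.exp(2 * q[j]) / s**2 + 1.0

        return ll + self.logprior_q(q), grad


# ---------------------------------------------------------------------------
# sampler


def _run_chain(target: _TargetDensity, cfg: SamplerConfig, rng: np.random.Generator):
    d = target.dim_q
    q = target.q_init() + cfg.init_jitter * rng.standard_normal(d) * 0.1
    log_rho = float(np.log(target.range_median) + cfg.init_jitter * rng.standard_normal() * 0.1)
    L = target.chol_for(log_rho)

    lp, grad = target.logpost_and_grad(q, L)
    if not np.isfinite(lp):
        ll = target.loglik(q, L)
        part = "data likelihood" if not np.isfinite(ll) else "prior density"
        raise RuntimeError(f"non-finite log-density at initialisation ({part})")

    W, D = cfg.warmup, cfg.draws
    minv = np.ones(d)
    eps = 0.1
    mu_da = np.log(10 * eps)
    h_bar, log_eps_bar, t_da = 0.0, np.log(eps), 0
    w1, w2 = int(0.15 * W), int(0.8 * W)
    q_acc = []

    rho_scale = 0.3
    asis_scale = {nm: 0.3 for nm in target.ls_names}
    samples = {"q": np.empty((D, d)), "log_rho": np.empty(D)}
    accept_sum = 0.0

    def reset_da(e0):
        nonlocal mu_da, h_bar, log_eps_bar, t_da
        mu_da, h_bar, log_eps_bar, t_da = np.log(10 * e0), 0.0, np.log(e0), 0

    for it in range(W + D):
        warm = it < W
        # ---- HMC on q
        p0 = rng.standard_normal(d) / np.sqrt(minv)
        n_leap = int(rng.integers(max(1, cfg.max_leapfrog // 2), cfg.max_leapfrog + 1))
        q_new, p_new = q.copy(), p0.copy()
        lp_new, g_new = lp, grad
        p_new = p_new + 0.5 * eps * g_new
        diverged = False
        for step in range(n_leap):
            q_new = q_new + eps * minv * p_new
            lp_new, g_new = target.logpost_and_grad(q_new, L)
            if not np.isfinite(lp_new):
                diverged = True
                break
            p_new = p_new + (eps if step < n_leap - 1 else 0.5 * eps) * g_new
        if diverged:
            a_prob = 0.0
        else:
            h0 = -lp + 0.5 * np.sum(p0**2 * minv)
            h1 = -lp_new + 0.5 * np.sum(p_new**2 * minv)
            a_prob = float(min(1.0, np.exp(min(0.0, h0 - h1))))
            if rng.random() < a_prob:
                q, lp, grad = q_new, lp_new, g_new
        if warm:
            t_da += 1
            frac = 1.0 / (t_da + 10)
            h_bar = (1 - frac) * h_bar + frac * (cfg.target_accept - a_prob)
            log_eps = mu_da - np.sqrt(t_da) / 0.05 * h_bar
            eps = float(np.exp(log_eps))
            w_da = t_da ** (-0.75)
            log_eps_bar = w_da * log_eps + (1 - w_da) * log_eps_bar
            if w1 <= it < w2:
                q_acc.append(q.copy())
            if it == w2 - 1 and len(q_acc) > 10:
                var = np.var(np.asarray(q_acc), axis=0)
                w_shrink = len(q_acc) / (len(q_acc) + 5.0)
                minv = np.clip(w_shrink * var + (1 - w_shrink) * 1.0, 1e-4, 1e4)
                reset_da(float(np.exp(log_eps_bar)))
            if it == W - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            accept_sum += a_prob

        # ---- Metropolis on the log range (non-centred: z_S held fixed)
        if target.sample_rho:
            lr_prop = log_rho + rho_scale * rng.standard_normal()
            L_prop = target.chol_for(lr_prop)
            lik = target.loglik(q, L)
            lik_prop = target.loglik(q, L_prop)
            log_r = lik_prop + target.logprior_rho(lr_prop) - lik - target.logprior_rho(log_rho)
            a = float(min(1.0, np.exp(min(0.0, log_r)))) if np.isfinite(log_r) else 0.0
            if rng.random() < a:
                log_rho, L = lr_prop, L_prop
                lp, grad = target.logpost_and_grad(q, L)
            if warm:
                rho_scale *= float(np.exp((a - 0.3) * (it + 1) ** (-0.6) * 3.0))

            # interweaved range move: S held fixed, z_S rotated accordingly
            z = q[target.slices["z_S"]]
            lr_prop = log_rho + rho_scale * rng.standard_normal()
            L_prop = target.chol_for(lr_prop)
            z_prop = solve_triangular(L_prop, L @ z, lower=True)
            log_jac = float(np.sum(np.log(np.diag(L))) - np.sum(np.log(np.diag(L_prop))))
            log_r = (
                -0.5 * (z_prop @ z_prop - z @ z)
                + target.logprior_rho(lr_prop)
                - target.logprior_rho(log_rho)
                + log_jac
            )
            a = float(min(1.0, np.exp(min(0.0, log_r)))) if np.isfinite(log_r) else 0.0
            if rng.random() < a:
                log_rho, L = lr_prop, L_prop
                q = q.copy()
                q[target.slices["z_S"]] = z_prop
                lp, grad = target.logpost_and_grad(q, L)

        # ---- interweaved scale moves: latents fixed, only prior/Jacobian enter
        changed = False
        for nm in target.ls_names:
            blk = {"log_sd_eta": "z_eta", "log_sd_tau": "z_tau", "log_sd_s": "z_S"}[nm]
            j = target.ls_index(nm)
            z = q[target.slices[blk]]
            delta = asis_scale[nm] * rng.standard_normal()
            ls_new = q[j] + delta
            z_prop = z * np.exp(-delta)
            s = target._ls_prior_scale(nm)
            log_r = (
                -0.5 * (z_prop @ z_prop - z @ z)
                - 0.5 * (np.exp(2 * ls_new) - np.exp(2 * q[j])) / s**2
                + delta
                - z.size * delta
            )
            a = float(min(1.0, np.exp(min(0.0, log_r)))) if np.isfinite(log_r) else 0.0
            if rng.random() < a:
                q = q.copy()
                q[j] = ls_new
                q[target.slices[blk]] = z_prop
                changed = True
            if warm:
                asis_scale[nm] *= float(np.exp((a - 0.35) * (it + 1) ** (-0.6) * 3.0))
        if changed:
            lp, grad = target.logpost_and_grad(q, L)

        if not warm:
            k = it - W
            samples["q"][k] = q
            samples["log_rho"][k] = log_rho

    return samples, eps, accept_sum / max(D, 1)


def fit(
    panel: PanelDataset,
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> Posterior:
    """Sample the joint posterior of the two-part model.

    Deterministic given ``(panel, prior, sampler, seed)``. Chains run
    sequentially from seeds spawned from ``seed``. Warns when any monitored
    R-hat exceeds 1.05.
    """
    prior = prior or PriorConfig()
    cfg = sampler or SamplerConfig()
    target = _TargetDensity(panel, prior, cfg)

    chains_q = np.empty((cfg.chains, cfg.draws, target.dim_q))
    chains_lr = np.empty((cfg.chains, cfg.draws))
    rates = []
    for c, ss in enumerate(np.random.SeedSequence(seed).spawn(cfg.chains)):
        rng = np.random.default_rng(ss)
        samples, eps, rate = _run_chain(target, cfg, rng)
        chains_q[c] = samples["q"]
        chains_lr[c] = samples["log_rho"]
        rates.append(rate)

    draws = _package_draws(target, chains_q, chains_lr, prior)
    post = Posterior(
        draws,
        list(panel.design.columns),
        meta={
            "seed": seed,
            "chains": cfg.chains,
            "draws": cfg.draws,
            "warmup": cfg.warmup,
            "accept_rates": rates,
            "latent_components": list(cfg.latent_components),
            "nu": prior.nu,
            "alpha_share": cfg.alpha_share,
        },
    )
    if cfg.chains >= 2:
        monitored = {
            k: v for k, v in post.scalar_map().items()
            if k.startswith("beta_") or k in ("sd_eta", "sd_tau", "sigma2", "rho")
        }
        bad = [k for k, v in monitored.items() if _rhat(v) > 1.05]
        if bad:
            warnings.warn(
                f"R-hat > 1.05 for {len(bad)} parameter(s), e.g. {bad[:4]}; "
                "consider more warmup/draws",
                stacklevel=2,
            )
    return post


def _package_draws(target: _TargetDensity, chains_q, chains_lr, prior: PriorConfig) -> dict:
    C, D, _ = chains_q.shape
    n, T = target.n, target.T
    sl = target.slices
    draws = {}

    def back_transform(block):
        b = block.copy()
        b0 = b[..., 0] - (b[..., 1:] * (target.mu_x / target.sx)).sum(axis=-1)
        rest = b[..., 1:] / target.sx
        return np.concatenate([b0[..., None], rest], axis=-1)

    draws["beta_binomial"] = back_transform(chains_q[:, :, sl["bB"]])
    draws["beta_poisson"] = back_transform(chains_q[:, :, sl["bP"]])

    def ls_col(nm):
        return np.exp(chains_q[:, :, target.ls_index(nm)])

    sd_eta = ls_col("log_sd_eta") if target.use_eta else np.zeros((C, D))
    sd_tau = ls_col("log_sd_tau") if target.use_temporal else np.zeros((C, D))
    sd_s = ls_col("log_sd_s") if target.use_spatial else np.zeros((C, D))
    draws["sd_eta"] = sd_eta
    draws["sd_tau"] = sd_tau
    draws["sigma2"] = sd_s**2
    if target.use_spatial:
        rho = np.exp(chains_lr)
        draws["rho"] = rho
        draws["kappa"] = np.sqrt(8.0 * prior.nu) / rho

    eta = np.zeros((C, D, n))
    if target.use_eta:
        eta = sd_eta[:, :, None] * chains_q[:, :, sl["z_eta"]]
    draws["eta"] = eta
    S = np.zeros((C, D, n))
    if target.use_spatial:
        # rho varies per draw: rebuild each factor, caching repeats
        for c in range(C):
            cache_key, Lc = None, None
            for k in range(D):
                lr = round(float(chains_lr[c, k]), 12)
                if lr != cache_key:
                    Lc = target.chol_for(lr)
                    cache_key = lr
                S[c, k] = sd_s[c, k] * (Lc @ chains_q[c, k, sl["z_S"]])
    draws["S"] = S
    tau = np.zeros((C, D, T))
    if target.use_temporal:
        walk = np.concatenate(
            [np.zeros((C, D, 1)), np.cumsum(chains_q[:, :, sl["z_tau"]], axis=-1)], axis=-1
        )
        tau = sd_tau[:, :, None] * (walk - walk.mean(axis=-1, keepdims=True))
    draws["tau"] = tau
    return draws


# ---------------------------------------------------------------------------
# diagnostics & summaries


def _split_chains(x: np.ndarray) -> np.ndarray:
    C, D = x.shape
    half = D // 2
    return np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)


def _rhat(x: np.ndarray) -> float:
    """Split-R-hat; 1.0 for chains with zero variance."""
    z = _split_chains(np.asarray(x, dtype=float))
    if np.allclose(z.var(axis=1), 0):
        return 1.0 if np.allclose(z.mean(axis=1), z.mean()) else np.inf
    m, d = z.shape
    w = z.var(axis=1, ddof=1).mean()
    b = d * z.mean(axis=1).var(ddof=1)
    var_plus = (d - 1) / d * w + b / d
    return float(np.sqrt(var_plus / w))


def _ess(x: np.ndarray) -> float:
    """Bulk effective sample size (arviz), 0 for zero-variance chains."""
    z = np.asarray(x, dtype=float)
    if np.allclose(z.var(axis=1), 0):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        val = float(az.ess(z))
    return 0.0 if not np.isfinite(val) else val


def diagnostics(posterior: Posterior) -> pd.DataFrame:
    """Split-R-hat and effective sample size per stored scalar.

    Flags scalars with R-hat > 1.05 or ESS < 100; constant chains are reported
    with R-hat 1 and ESS 0 (flagged).
    """
    if posterior.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    if posterior.n_draws < 100:
        raise ValueError("diagnostics require at least 100 draws per chain")
    rows = []
    for name, arr in posterior.scalar_map().items():
        r = _rhat(arr)
        e = _ess(arr)
        rows.append(
            {"parameter": name, "rhat": r, "ess": e, "flagged": bool(r > 1.05 or e < 100)}
        )
    return pd.DataFrame(rows).set_index("parameter")


def summarize(posterior: Posterior, level: float = 0.95, part: str = "binomial") -> pd.DataFrame:
    """Odds/rate-ratio table: posterior mean OR, equal-tailed interval, unity flag.

    ``contains_one`` mirrors the reporting convention where an effect is called
    significant at the level iff its interval excludes 1.
    """
    if level not in (0.90, 0.95):
        raise ValueError("level must be 0.90 or 0.95")
    if part not in ("binomial", "poisson"):
        raise ValueError("part must be 'binomial' or 'poisson'")
    key = "beta_binomial" if part == "binomial" else "beta_poisson"
    if key not in posterior.draws or posterior.draws[key].size == 0:
        raise ValueError("posterior holds no coefficient draws")
    ors = np.exp(posterior.stacked(key))  # (draws, p+1)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo = np.quantile(ors, lo_q, axis=0)
    hi = np.quantile(ors, hi_q, axis=0)
    tab = pd.DataFrame(
        {
            "or_mean": ors.mean(axis=0),
            "or_low": lo,
            "or_high": hi,
            "contains_one": (lo <= 1.0) & (hi >= 1.0),
        },
        index=pd.Index(posterior.term_names, name="term"),
    )
    tab["significant"] = ~tab["contains_one"]
    return tab
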