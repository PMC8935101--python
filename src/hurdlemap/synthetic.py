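"""Synthetic census-tract geographies, covariates, latent fields, and counts.

Everything downstream of data collection is testable without any download:
this module fabricates a small-city geography (Voronoi tracts over a square
extent), tract covariates whose marginals match the published descriptives of
the study region, latent spatial/temporal/IID risk fields, and report counts
whose observation process embodies socio-economically driven under-reporting.

Every generator is a pure function of its inputs and a seed; stage seeds are
spawned from the scenario seed through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from . import covariates as cov
from .matern import MaternParams, kappa_from_range, sample_field
from .model import LatentEffects, PanelDataset

OBS_MODES = ("hurdle", "binomial")

#: target (mean, sd) of the generated covariate marginals, percentages
COVARIATE_MARGINALS = {
    "unemployment": (24.46, 9.47),
    "manual_workers": (52.24, 17.42),
    "temporary_workers": (24.84, 8.27),
    "without_schooling": (26.0, 7.0),
    "without_schooling_young": (15.0, 5.0),
    "without_internet": (33.38, 9.73),
    "housing45": (4.25, 5.82),
    "housing4560": (10.68, 5.12),
    "foreign": (21.51, 15.46),
}

#: Dirichlet weights splitting the foreign percentage into origins
#: (Africa, South America, Asia, other), proportional to the published means
_FOREIGN_SPLIT_ALPHA = np.array([6.73, 12.98, 1.54, 0.55]) * 0.25

#: one shared deprivation factor drives the six indicators
_DEPRIVATION_LOADING = 0.7


@dataclass
class TractFrame:
    """Static per-tract records: geometry, centroid, population, covariates."""

    table: pd.DataFrame  # index tract_id; columns x, y, population, covariates...
    geometry: list  # shapely polygons aligned with table rows

    def __post_init__(self) -> None:
        if len(self.table) != len(self.geometry):
            raise ValueError("table and geometry lengths differ")

    @property
    def n_tracts(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def copy(self) -> "TractFrame":
        return TractFrame(self.table.copy(), list(self.geometry))


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic data set.

    ``true_betas_*`` map design-column names (see
    :data:`hurdlemap.covariates.DESIGN_COLUMNS`, plus ``"intercept"``) to
    generative coefficients; unnamed columns get 0. ``obs_mode`` selects the
    observation process: ``"hurdle"`` draws a tract-period reporting gate and
    then a count, ``"binomial"`` draws the count directly from the reporting
    part's binomial law.
    """

    n_tracts: int = 80
    n_periods: int = 7
    extent: float = 10_000.0
    true_betas_binomial: dict = field(default_factory=dict)
    true_betas_poisson: dict = field(default_factory=dict)
    matern: MaternParams = field(
        default_factory=lambda: MaternParams(sigma2=0.1, nu=1.0, kappa=kappa_from_range(1.0, 2000.0))
    )
    var_eta: float = 0.05
    var_tau: float = 0.02
    seed: int = 0
    missing_fraction: float = 0.05
    obs_mode: str = "hurdle"
    drop_zero_rows: bool = False

    def __post_init__(self) -> None:
        if self.n_tracts < 4:
            raise ValueError("n_tracts must be at least 4 for quintile coding to be meaningful")
        if self.n_tracts < 10:
            warnings.warn("fewer than 10 tracts: quintile boundaries will be crude", stacklevel=2)
        if self.n_periods < 1 or self.extent <= 0:
            raise ValueError("n_periods must be >= 1 and extent > 0")
        if self.var_eta < 0 or self.var_tau < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.obs_mode not in OBS_MODES:
            raise ValueError(f"obs_mode must be one of {OBS_MODES}")


def reference_betas() -> dict:
    """Reporting-part generative coefficients: log odds-ratios of the published fit."""
    ors = {
        "deprivation_q45": 0.573,
        "unemployment_q2": 1.009,
        "unemployment_q3": 1.196,
        "unemployment_q4": 0.846,
        "unemployment_q5": 0.994,
        "housing45": 0.894,
        "housing4560": 0.995,
        "foreign": 1.028,
        "foreign_africa": 0.976,
        "foreign_south_america": 0.978,
        "foreign_asia": 1.146,
        "manual_workers": 1.007,
        "temporary_workers": 1.000,
        "without_schooling_q45": 0.787,
        "without_schooling_young_q123": 0.887,
        "without_internet": 0.991,
    }
    return {k: float(np.log(v)) for k, v in ors.items()}


def default_scenario(**overrides) -> SyntheticScenario:
    """The default study conditions: a small-city 80-tract, 7-period panel.

    The reporting part uses the published odds-ratios as generative truth with
    a tract-period gate probability around 0.7; the count part has intercept
    log 5 (about five reports per tract-period when the gate is open) and no
    covariate effects — covariates drive reporting propensity, not incident
    intensity.
    """
    betas_b = reference_betas()
    betas_b["intercept"] = 1.6
    betas_p = {"intercept": float(np.log(5.0))}
    base = dict(true_betas_binomial=betas_b, true_betas_poisson=betas_p)
    base.update(overrides)
    return SyntheticScenario(**base)


def _spawn(seed, n: int):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def generate_tracts(n_tracts: int, extent: float, seed: int) -> TractFrame:
    """Voronoi tessellation of uniform points in [0, extent]^2.

    Centroid points are mirrored across the four extent edges before
    tessellating, so each interior cell comes out exactly clipped to the
    square. Populations are drawn log-uniformly in [500, 3000].
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be a positive integer")
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, extent, size=(n_tracts, 2))
    mirrors = np.concatenate(
        [
            pts * [-1, 1],
            pts * [1, -1],
            np.column_stack([2 * extent - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * extent - pts[:, 1]]),
        ]
    )
    vor = Voronoi(np.concatenate([pts, mirrors]))
    square = box(0.0, 0.0, extent, extent)
    polys = []
    for i in range(n_tracts):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # Voronoi cells are convex: order vertices by angle around their mean
        ang = np.arctan2(verts[:, 1] - verts[:, 1].mean(), verts[:, 0] - verts[:, 0].mean())
        poly = Polygon(verts[np.argsort(ang)]).intersection(square)
        polys.append(poly)
    populations = np.round(np.exp(rng.uniform(np.log(500.0), np.log(3000.0), n_tracts))).astype(int)
    table = pd.DataFrame(
        {"x": pts[:, 0], "y": pts[:, 1], "population": populations},
        index=pd.RangeIndex(1, n_tracts + 1, name="tract_id"),
    )
    return TractFrame(table, polys)


def generate_covariates(tracts: TractFrame, seed: int) -> TractFrame:
    """Attach the 13 raw covariates, marginals near the published descriptives.

    The six deprivation indicators load on one shared latent factor (so the
    composite deprivation index is meaningful); foreign-origin subgroup
    percentages are a Dirichlet split of the overall foreign percentage, which
    enforces their sum constraint by construction. All percentages are clipped
    to [0, 100].
    """
    if tracts.n_tracts == 0:
        raise ValueError("tract frame is empty")
    rng = np.random.default_rng(seed)
    n = tracts.n_tracts
    out = tracts.copy()
    f = rng.standard_normal(n)  # shared deprivation factor
    lam = _DEPRIVATION_LOADING
    for name in cov.DEPRIVATION_INDICATORS:
        mu, sd = COVARIATE_MARGINALS[name]
        z = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        out.table[name] = np.clip(mu + sd * z, 0.0, 100.0)
    for name in ("housing45", "housing4560", "foreign"):
        mu, sd = COVARIATE_MARGINALS[name]
        out.table[name] = np.clip(mu + sd * rng.standard_normal(n), 0.0, 100.0)
    w = rng.dirichlet(_FOREIGN_SPLIT_ALPHA, size=n)
    foreign = out.table["foreign"].to_numpy()
    out.table["foreign_africa"] = foreign * w[:, 0]
    out.table["foreign_south_america"] = foreign * w[:, 1]
    out.table["foreign_asia"] = foreign * w[:, 2]
    return out


def simulate_latent_fields(
    tracts: TractFrame,
    n_periods: int,
    matern: MaternParams,
    var_eta: float,
    var_tau: float,
    seed: int,
) -> LatentEffects:
    """Draw the three latent components of the linear predictors.

    S is one Matérn Gaussian-field realisation at the tract centroids; eta is
    IID N(0, var_eta); tau is a first-order random walk with innovation
    variance var_tau, centred to sum to zero. Zero variances give exactly-zero
    components.
    """
    if var_eta < 0 or var_tau < 0:
        raise ValueError("variances must be non-negative")
    ss = _spawn(seed, 3)
    n = tracts.n_tracts
    S = sample_field(tracts.centroids, matern, np.random.default_rng(ss[0]))
    eta = (
        np.sqrt(var_eta) * np.random.default_rng(ss[1]).standard_normal(n)
        if var_eta > 0
        else np.zeros(n)
    )
    if var_tau > 0 and n_periods > 1:
        inc = np.sqrt(var_tau) * np.random.default_rng(ss[2]).standard_normal(n_periods - 1)
        walk = np.concatenate([[0.0], np.cumsum(inc)])
        tau = walk - walk.mean()
    else:
        tau = np.zeros(n_periods)
    return LatentEffects(eta=eta, tau=tau, S=S)


def _beta_vector(named: dict, columns) -> np.ndarray:
    unknown = set(named) - set(columns) - {"intercept"}
    if unknown:
        raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
    vec = np.zeros(len(columns) + 1)
    vec[0] = named.get("intercept", 0.0)
    for j, c in enumerate(columns):
        vec[j + 1] = named.get(c, 0.0)
    return vec


def simulate_observations(
    tracts: TractFrame,
    effects: LatentEffects,
    scenario: SyntheticScenario,
    design: pd.DataFrame | None = None,
) -> PanelDataset:
    """Draw the tract x period panel of report counts under the scenario.

    In ``"hurdle"`` mode, each tract-period draws a reporting gate
    g ~ Bernoulli(logistic(l1)) and, when the gate is open, a count
    Y ~ Poisson(exp(l2)); closed gates yield structural zeros — the endogenous
    selection the model is built to absorb. In ``"binomial"`` mode the count
    is drawn directly as Y ~ Binomial(population, logistic(l1)), the reporting
    part's own law. Both predictors share eta + S + tau.

    A ``missing_fraction`` of tract-periods is removed completely at random
    (unbalanced panel); with ``drop_zero_rows`` zero counts are additionally
    absent rather than explicit rows. Ground truth (latents, gates, coefficient
    vectors) is attached to ``PanelDataset.truth`` for recovery tests.
    """
    if design is None:
        design = cov.build_design_matrix(tracts.table)
    X = design.to_numpy(dtype=float)
    n, T = tracts.n_tracts, scenario.n_periods
    if effects.eta.size != n or effects.tau.size != T:
        raise ValueError("latent fields are not conformable with tracts/periods")
    bB = _beta_vector(scenario.true_betas_binomial, design.columns)
    bP = _beta_vector(scenario.true_betas_poisson, design.columns)
    u = effects.eta + effects.S
    l1 = bB[0] + (X @ bB[1:])[:, None] + u[:, None] + effects.tau[None, :]
    l2 = bP[0] + (X @ bP[1:])[:, None] + u[:, None] + effects.tau[None, :]
    if scenario.obs_mode == "hurdle" and np.max(l2) > 30:
        raise FloatingPointError(
            "Poisson log-rate exceeds 30; rescale the predictors (smaller "
            "coefficients/latent variances) to avoid exp overflow"
        )
    rng = np.random.default_rng(_spawn(scenario.seed, 4)[3])
    pops = tracts.table["population"].to_numpy()
    with np.errstate(over="ignore"):
        p1 = 1.0 / (1.0 + np.exp(-l1))
    if scenario.obs_mode == "hurdle":
        gates = rng.random((n, T)) < p1
        counts = np.where(gates, rng.poisson(np.exp(l2)), 0)
    else:
        gates = np.ones((n, T), dtype=bool)
        counts = rng.binomial(pops[:, None], p1)
    counts = np.minimum(counts, pops[:, None])  # counts may never exceed population

    tract_ids = np.repeat(design.index.to_numpy(), T)
    periods = np.tile(np.arange(1, T + 1), n)
    obs = pd.DataFrame({"tract_id": tract_ids, "period": periods, "count": counts.ravel()})
    keep = rng.random(len(obs)) >= scenario.missing_fraction
    # every period must survive somewhere so labels stay contiguous
    for t in range(1, T + 1):
        rows = np.flatnonzero(obs["period"].to_numpy() == t)
        if not keep[rows].any():
            keep[rows[0]] = True
    obs = obs[keep]
    if scenario.drop_zero_rows:
        obs = obs[obs["count"] > 0]
    obs = obs.reset_index(drop=True)

    return PanelDataset(
        obs=obs,
        n_trials=tracts.table["population"],
        design=design,
        centroids=tracts.centroids,
        truth={
            "effects": effects,
            "gates": gates,
            "beta_binomial": bB,
            "beta_poisson": bP,
            "scenario": scenario,
        },
    )


def simulate_scenario(scenario: SyntheticScenario):
    """Run the full generator chain; returns (tracts, effects, panel)."""
    ss = _spawn(scenario.seed, 4)
    tracts = generate_tracts(scenario.n_tracts, scenario.extent, ss[0])
    tracts = generate_covariates(tracts, ss[1])
    effects = simulate_latent_fields(
        tracts, scenario.n_periods, scenario.matern, scenario.var_eta, scenario.var_tau, ss[2]
    )
    panel = simulate_observations(tracts, effects, scenario)
    return tracts, effects, panel


def with_region_shift(effects: LatentEffects, tracts: TractFrame, center: np.ndarray,
                      radius: float, shift: float) -> tuple[LatentEffects, np.ndarray]:
    """Add ``shift`` to S for tracts within ``radius`` of ``center``.

    Returns the shifted effects and the boolean mask of affected tracts —
    the known-truth elevated-risk region for detection tests.
    """
    d = np.linalg.norm(tracts.centroids - np.asarray(center)[None, :], axis=1)
    mask = d <= radius
    S = effects.S.copy()
    S[mask] += shift
    return replace(effects, S=S), mask
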