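"""Smoothed relative risks, exceedance probabilities, and hotspot maps.

The mapped quantity is the model-unexplained residual risk of a tract:
RR_i = exp(S_i + eta_i) per posterior draw — the spatially structured plus
unstructured latent field after covariate adjustment, with the temporal effect
excluded (maps are time-aggregated). The exceedance probability
PRP_i = Pr(RR_i > 1) is the fraction of posterior draws strictly above 1;
tracts with PRP above 0.8 are flagged hotspots and below 0.2 coldspots
(the Richardson interpretation rule), anything else — including the boundary
values exactly — is uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import Posterior
from .io import write_geojson

LABELS = ("hotspot", "coldspot", "uncertain")


@dataclass
class RiskSurface:
    """Per-tract posterior risk summary: RR, interval, PRP, hotspot label."""

    table: pd.DataFrame  # index tract_id; rr_mean, rr_low, rr_high, prp, hotspot_label

    def __post_init__(self) -> None:
        req = {"rr_mean", "rr_low", "rr_high", "prp", "hotspot_label"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"risk surface table must have columns {sorted(req)}")
        if ((self.table["prp"] < 0) | (self.table["prp"] > 1)).any():
            raise ValueError("exceedance probabilities must lie in [0, 1]")


def smoothed_rr(
    posterior: Posterior,
    components: tuple = ("spatial", "eta"),
    part: str = "binomial",
    design=None,
) -> np.ndarray:
    """Per-tract relative-risk draws, shape (n_draws_total, n_tracts).

    Default is the residual risk exp(S + eta). Passing the tract-level
    ``design`` matrix adds each tract's fixed-effect contribution (centred
    across tracts) for a full-risk map; ``part`` selects whose coefficients and
    latent scaling are used — the latent field itself is shared between parts.
    """
    if part not in ("binomial", "poisson"):
        raise ValueError("part must be 'binomial' or 'poisson'")
    for key in ("S", "eta"):
        if key not in posterior.draws:
            raise KeyError(f"posterior lacks latent draws {key!r}")
    log_rr = 0.0
    if "spatial" in components:
        log_rr = log_rr + posterior.stacked("S")
    if "eta" in components:
        log_rr = log_rr + posterior.stacked("eta")
    log_rr = np.atleast_2d(log_rr)
    if part == "poisson":
        alpha = float(posterior.meta.get("alpha_share", 1.0))
        log_rr = alpha * log_rr
    if design is not None:
        beta = posterior.stacked("beta_binomial" if part == "binomial" else "beta_poisson")
        contrib = beta[:, 1:] @ np.asarray(design, dtype=float).T
        log_rr = log_rr + contrib - contrib.mean(axis=1, keepdims=True)
    return np.exp(log_rr)


def exceedance_prob(rr_draws: np.ndarray):
    """Fraction of draws strictly greater than 1, per tract.

    Accepts a (draws,) vector for a single tract (returns a float) or a
    (draws, n_tracts) matrix (returns a length-n vector).
    """
    rr = np.asarray(rr_draws, dtype=float)
    single = rr.ndim == 1
    if single:
        rr = rr[:, None]
    if rr.shape[0] < 1 or rr.size == 0:
        raise ValueError("need at least one draw per tract")
    out = (rr > 1.0).mean(axis=0)
    return float(out[0]) if single else out


def classify_hotspots(probs, hi_cutoff: float = 0.8, lo_cutoff: float = 0.2) -> np.ndarray:
    """Richardson-rule labels: hotspot iff PRP > hi, coldspot iff PRP < lo.

    Boundary values (PRP exactly at a cutoff) are 'uncertain'.
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("exceedance probabilities must lie in [0, 1]")
    if not 0 <= lo_cutoff <= hi_cutoff <= 1:
        raise ValueError("cutoffs must satisfy 0 <= lo <= hi <= 1")
    labels = np.where(p > hi_cutoff, "hotspot", np.where(p < lo_cutoff, "coldspot", "uncertain"))
    return labels


def build_risk_surface(
    posterior: Posterior,
    tract_ids,
    level: float = 0.95,
    hi_cutoff: float = 0.8,
    lo_cutoff: float = 0.2,
    part: str = "binomial",
) -> RiskSurface:
    """Summarise posterior latent draws into a per-tract risk table."""
    rr = smoothed_rr(posterior, part=part)
    if rr.shape[1] != len(tract_ids):
        raise ValueError("tract_ids length does not match the posterior's tract count")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    prp = exceedance_prob(rr)
    table = pd.DataFrame(
        {
            "rr_mean": rr.mean(axis=0),
            "rr_low": np.quantile(rr, lo_q, axis=0),
            "rr_high": np.quantile(rr, hi_q, axis=0),
            "prp": prp,
            "hotspot_label": classify_hotspots(prp, hi_cutoff, lo_cutoff),
        },
        index=pd.Index(tract_ids, name="tract_id"),
    )
    return RiskSurface(table)


def export_layers(tracts, surface: RiskSurface, out_path, render_png: bool = True) -> dict:
    """Write the map-ready layers: GeoJSON, CSV twin, optional PNG choropleth.

    ``tracts`` is a :class:`hurdlemap.synthetic.TractFrame` (or anything with a
    tract-id-indexed table and aligned geometry list). Returns the written paths.
    """
    from pathlib import Path

    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    missing = [t for t in surface.table.index if t not in set(tracts.table.index)]
    if missing:
        raise KeyError(f"no geometry for tract(s): {missing[:5]}")
    order = [list(tracts.table.index).index(t) for t in surface.table.index]
    geoms = [tracts.geometry[i] for i in order]
    geo_path = out / "risk_surface.geojson"
    csv_path = out / "risk_surface.csv"
    write_geojson(surface.table, geoms, geo_path)
    surface.table.to_csv(csv_path)
    paths = {"geojson": geo_path, "csv": csv_path}
    if render_png:
        paths["png"] = _render_choropleth(geoms, surface.table, out / "risk_surface.png")
    return paths


def _render_choropleth(geoms, table, path):
    """Two-panel map (RR left, PRP right); cosmetic output for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for ax, col, cmap, title in (
        (axes[0], "rr_mean", "viridis", "smoothed relative risk"),
        (axes[1], "prp", "magma", "Pr(RR > 1)"),
    ):
        patches = [MplPolygon(np.asarray(g.exterior.coords)) for g in geoms]
        coll = PatchCollection(patches, cmap=cmap, edgecolor="white", linewidth=0.3)
        coll.set_array(table[col].to_numpy())
        ax.add_collection(coll)
        ax.autoscale()
        ax.set_aspect("equal")
        ax.set_title(title)
        fig.colorbar(coll, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
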