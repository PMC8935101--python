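"""Deprivation index and fixed-effects design matrix construction.

The deprivation index summarises six tract-level socioeconomic indicators
(unemployment, manual workers, temporary workers, without compulsory schooling,
without compulsory schooling among the young, without internet access) as the
first principal component of the standardised indicators — the standard MEDEA
small-area construction — sign-oriented so that higher values mean higher
deprivation (positive loading on unemployment).

Categorised covariates use tract-distribution quintiles:

* unemployment: four dummies Q2..Q5 against a Q1 reference;
* deprivation index and without-compulsory-schooling: a single Q4–Q5 dummy
  against a Q1–Q3 reference;
* without-compulsory-schooling (young): a single Q1–Q3 dummy against a Q4–Q5
  reference.

Remaining covariates enter as raw percentages. Covariates are tract-level
constants (single-census measurements) replicated across periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the six indicators combined into the deprivation index
DEPRIVATION_INDICATORS = [
    "unemployment",
    "manual_workers",
    "temporary_workers",
    "without_schooling",
    "without_schooling_young",
    "without_internet",
]

#: raw covariate columns a tract table must carry (13 of Table-1 type)
RAW_COVARIATES = [
    "unemployment",
    "housing45",
    "housing4560",
    "foreign",
    "foreign_africa",
    "foreign_south_america",
    "foreign_asia",
    "manual_workers",
    "temporary_workers",
    "without_schooling",
    "without_schooling_young",
    "without_internet",
]

#: fixed design-matrix column order: 16 columns forming 13 coefficient terms
#: (1 grouped deprivation dummy, 4 unemployment dummies, 9 raw percentages,
#:  2 grouped schooling dummies)
DESIGN_COLUMNS = [
    "deprivation_q45",
    "unemployment_q2",
    "unemployment_q3",
    "unemployment_q4",
    "unemployment_q5",
    "housing45",
    "housing4560",
    "foreign",
    "foreign_africa",
    "foreign_south_america",
    "foreign_asia",
    "manual_workers",
    "temporary_workers",
    "without_schooling_q45",
    "without_schooling_young_q123",
    "without_internet",
]

GROUPINGS = ("Q1_ref_four_dummies", "Q123_ref_vs_Q45", "Q45_ref_vs_Q123")


@dataclass(frozen=True)
class QuintileScheme:
    """How one covariate is quintile-categorised and reference-coded."""

    variable: str
    grouping: str
    boundaries: tuple = field(default=None)  # 20/40/60/80th percentiles, or None = from data

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}; expected one of {GROUPINGS}")
        if self.boundaries is not None:
            b = tuple(float(x) for x in self.boundaries)
            if len(b) != 4 or any(b[i] > b[i + 1] for i in range(3)):
                raise ValueError("boundaries must be four non-decreasing cut values")
            object.__setattr__(self, "boundaries", b)


def default_schemes() -> dict[str, QuintileScheme]:
    """The categorisation schemes used in the published model."""
    return {
        "deprivation": QuintileScheme("deprivation", "Q123_ref_vs_Q45"),
        "unemployment": QuintileScheme("unemployment", "Q1_ref_four_dummies"),
        "without_schooling": QuintileScheme("without_schooling", "Q123_ref_vs_Q45"),
        "without_schooling_young": QuintileScheme("without_schooling_young", "Q45_ref_vs_Q123"),
    }


def compute_deprivation_index(indicators: pd.DataFrame) -> pd.Series:
    """First principal component of the six standardised deprivation indicators.

    Sign-oriented so that the loading on unemployment is positive (higher index
    = more deprived); zero mean by construction.

    Raises
    ------
    ValueError
        If a column is missing, non-numeric/NaN, or has zero variance.
    """
    missing = [c for c in DEPRIVATION_INDICATORS if c not in indicators.columns]
    if missing:
        raise ValueError(f"missing deprivation indicator column(s): {missing}")
    X = indicators[DEPRIVATION_INDICATORS].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("deprivation indicators contain missing values")
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    if np.any(sd <= 0):
        bad = [c for c, s in zip(DEPRIVATION_INDICATORS, sd) if s <= 0]
        raise ValueError(f"degenerate (constant) indicator column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    # first right singular vector = leading PC loadings
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    if loadings[DEPRIVATION_INDICATORS.index("unemployment")] < 0:
        loadings = -loadings
    return pd.Series(Z @ loadings, index=indicators.index, name="deprivation")


def quintile_categorize(values, scheme: QuintileScheme) -> np.ndarray:
    """Assign quintile-based category codes per the scheme.

    For ``Q1_ref_four_dummies`` returns integer quintiles 1..5; for the grouped
    schemes returns 0 (reference) / 1 (indicator). Boundaries are the
    20/40/60/80th percentiles unless fixed in the scheme; intervals are
    left-closed with ties resolved to the lower quintile.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if scheme.boundaries is not None:
        bounds = np.asarray(scheme.boundaries)
    else:
        if len(v) < 5:
            warnings.warn(
                f"only {len(v)} observations for quintile boundaries of "
                f"{scheme.variable!r}; using best-effort percentiles",
                stacklevel=2,
            )
        bounds = np.percentile(v, [20, 40, 60, 80])
    # ties to the lower quintile: count boundaries strictly below the value
    q = 1 + (v[:, None] > bounds[None, :]).sum(axis=1)
    if scheme.grouping == "Q1_ref_four_dummies":
        return q
    if scheme.grouping == "Q123_ref_vs_Q45":
        return (q >= 4).astype(int)
    return (q <= 3).astype(int)  # Q45_ref_vs_Q123


def build_design_matrix(
    tract_table: pd.DataFrame,
    schemes: dict[str, QuintileScheme] | None = None,
) -> pd.DataFrame:
    """Tract-level fixed-effects design matrix with the documented column order.

    Computes the deprivation index if a ``deprivation`` column is not already
    present. Returns one row per tract (covariates are period-constant; expand
    with :func:`expand_to_panel` for per-observation rows).

    Raises
    ------
    KeyError
        Naming any missing raw covariate column.
    """
    missing = [c for c in RAW_COVARIATES if c not in tract_table.columns]
    if missing:
        raise KeyError(f"tract table is missing covariate column(s): {missing}")
    schemes = schemes or default_schemes()
    tbl = tract_table
    dep = (
        tbl["deprivation"]
        if "deprivation" in tbl.columns
        else compute_deprivation_index(tbl)
    )

    out = pd.DataFrame(index=tbl.index)
    out["deprivation_q45"] = quintile_categorize(dep, schemes["deprivation"])
    uq = quintile_categorize(tbl["unemployment"], schemes["unemployment"])
    for k in range(2, 6):
        out[f"unemployment_q{k}"] = (uq == k).astype(int)
    for col in (
        "housing45",
        "housing4560",
        "foreign",
        "foreign_africa",
        "foreign_south_america",
        "foreign_asia",
        "manual_workers",
        "temporary_workers",
    ):
        out[col] = tbl[col].astype(float)
    out["without_schooling_q45"] = quintile_categorize(
        tbl["without_schooling"], schemes["without_schooling"]
    )
    out["without_schooling_young_q123"] = quintile_categorize(
        tbl["without_schooling_young"], schemes["without_schooling_young"]
    )
    out["without_internet"] = tbl["without_internet"].astype(float)
    return out[DESIGN_COLUMNS]


def expand_to_panel(design: pd.DataFrame, obs: pd.DataFrame) -> pd.DataFrame:
    """Replicate tract-level design rows to one row per (tract, period) observation."""
    X = design.loc[obs["tract_id"]].reset_index(drop=True)
    X.index = pd.MultiIndex.from_frame(obs[["tract_id", "period"]])
    return X
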