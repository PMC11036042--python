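"""The ecological risk index chain: C_i, N_i, D_i, E_i, V_i, R_i -> ERI.

Per sample-grid cell and land-cover class *i* (all areas km², perimeters km,
evaluated from within-cell patches):

    fragmentation   C_i = n_i / A_i                          [km^-2]
    isolation       N_i = (A / (2 A_i)) * sqrt(n_i / A)      [dimensionless]
    dominance       D_i = (P_i/P_tot + n_i/N_tot)/4 + (A_i/A)/2   in [0, 1]
    disturbance     E_i = a C_i + b N_i + c D_i,  (a, b, c) = (0.5, 0.3, 0.2)
    vulnerability   V_i = (6 - rank_i) / 15,  rank 1 = most vulnerable
    loss            R_i = E_i * V_i
    risk            ERI = sum_i (A_i / A) * R_i     at the cell center

The default vulnerability ordering for the five arid-land classes puts bare
wasteland (desert) first — most vulnerable — then water, grassland,
impervious, cropland.  Because C_i carries units of km^-2, the ERI is
unit-dependent: all computations here fix km / km² so results are comparable
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landcover import SampleGrid
from .patches import PatchTable

__all__ = [
    "DEFAULT_VULNERABILITY_RANKS",
    "DEFAULT_WEIGHTS",
    "vulnerability_scores",
    "fragmentation",
    "isolation",
    "dominance",
    "disturbance",
    "loss",
    "RiskGrid",
    "compute_risk_grid",
]

#: rank 1 = most vulnerable ... 5 = least vulnerable
DEFAULT_VULNERABILITY_RANKS: dict[str, int] = {
    "wasteland": 1,
    "water": 2,
    "grassland": 3,
    "impervious": 4,
    "cropland": 5,
}

#: weights (a, b, c) of fragmentation, isolation, dominance in E_i
DEFAULT_WEIGHTS: tuple[float, float, float] = (0.5, 0.3, 0.2)


def vulnerability_scores(ranks: Mapping[str, int] | None = None) -> dict[str, float]:
    """Normalized vulnerability V_i from rank positions (1 = most vulnerable).

    Raw score is ``m + 1 - rank`` over the ``m`` ranked classes; scores are
    divided by their sum so that sum(V_i) = 1.
    """
    if ranks is None:
        ranks = DEFAULT_VULNERABILITY_RANKS
    m = len(ranks)
    if sorted(ranks.values()) != list(range(1, m + 1)):
        raise ValueError(f"ranks must be a permutation of 1..{m}, got {dict(ranks)}")
    raw = {name: m + 1 - r for name, r in ranks.items()}
    total = sum(raw.values())
    return {name: v / total for name, v in raw.items()}


def fragmentation(n_i, a_i):
    """C_i = n_i / A_i (patches per km²)."""
    n_i, a_i = np.asarray(n_i, float), np.asarray(a_i, float)
    if np.any(a_i <= 0):
        raise ValueError("fragmentation undefined for zero class area")
    return n_i / a_i


def isolation(n_i, a_i, a):
    """N_i = (A / (2 A_i)) * sqrt(n_i / A)."""
    n_i, a_i, a = np.asarray(n_i, float), np.asarray(a_i, float), np.asarray(a, float)
    if np.any(a_i <= 0) or np.any(a <= 0):
        raise ValueError("isolation undefined for zero areas")
    return a / (2.0 * a_i) * np.sqrt(n_i / a)


def dominance(n_i, p_i, a_i, n_tot, p_tot, a):
    """D_i = (P_i/P_tot + n_i/N_tot)/4 + (A_i/A)/2, in [0, 1]."""
    n_tot, p_tot, a = (np.asarray(v, float) for v in (n_tot, p_tot, a))
    if np.any(n_tot <= 0) or np.any(p_tot <= 0) or np.any(a <= 0):
        raise ValueError("dominance undefined for zero cell totals")
    p_i, n_i, a_i = (np.asarray(v, float) for v in (p_i, n_i, a_i))
    return (p_i / p_tot + n_i / n_tot) / 4.0 + (a_i / a) / 2.0


def disturbance(c_i, n_i, d_i, weights: Sequence[float] = DEFAULT_WEIGHTS):
    """E_i = a C_i + b N_i + c D_i with a + b + c = 1."""
    a, b, c = (float(w) for w in weights)
    if abs(a + b + c - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {a + b + c}")
    return a * np.asarray(c_i, float) + b * np.asarray(n_i, float) + c * np.asarray(d_i, float)


def loss(e_i, v_i):
    """R_i = E_i * V_i."""
    return np.asarray(e_i, float) * np.asarray(v_i, float)


@dataclass
class RiskGrid:
    """Per-cell risk components and the scalar ERI at each cell center.

    ``cells``: cell_id, row, col, x, y, valid_area_km2, eri.
    ``per_class``: the full component chain per (cell, class).
    """

    cells: pd.DataFrame
    per_class: pd.DataFrame
    weights: tuple[float, float, float]
    scores: dict[str, float] = field(default_factory=dict)

    def points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, eri) arrays — the point support for interpolation."""
        return (
            self.cells["x"].to_numpy(),
            self.cells["y"].to_numpy(),
            self.cells["eri"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def compute_risk_grid(
    patches: PatchTable,
    grid: SampleGrid,
    ranks: Mapping[str, int] | None = None,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> RiskGrid:
    """Compose the full index chain for every sample-grid cell.

    Each cell's indices are computed locally, from the patches clipped to
    that cell; the cell's ERI is the class-area-weighted sum of the per-class
    loss indices.
    """
    scores = vulnerability_scores(ranks)
    df = patches.merged()
    if df.empty:
        raise ValueError("empty patch table")
    missing = set(df["class_name"]) - set(scores)
    if missing:
        raise ValueError(f"no vulnerability rank for classes: {sorted(missing)}")

    c_i = fragmentation(df["n_patches"], df["area_km2"])
    n_i = isolation(df["n_patches"], df["area_km2"], df["area_tot_km2"])
    d_i = dominance(
        df["n_patches"], df["perimeter_km"], df["area_km2"],
        df["n_tot"], df["perim_tot_km"], df["area_tot_km2"],
    )
    e_i = disturbance(c_i, n_i, d_i, weights)
    v_i = df["class_name"].map(scores).to_numpy()
    r_i = loss(e_i, v_i)
    share = df["area_km2"] / df["area_tot_km2"]

    per_class = df[["cell_id", "class_code", "class_name", "n_patches", "area_km2", "perimeter_km"]].copy()
    per_class["C_i"] = np.asarray(c_i)
    per_class["N_i"] = np.asarray(n_i)
    per_class["D_i"] = np.asarray(d_i)
    per_class["E_i"] = np.asarray(e_i)
    per_class["V_i"] = v_i
    per_class["R_i"] = np.asarray(r_i)
    per_class["area_share"] = np.asarray(share)

    eri = (
        per_class.assign(term=per_class["area_share"] * per_class["R_i"])
        .groupby("cell_id")["term"]
        .sum()
        .rename("eri")
    )
    cells = grid.cells.merge(eri, on="cell_id", how="inner")
    return RiskGrid(cells, per_class, tuple(float(w) for w in weights), scores)
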