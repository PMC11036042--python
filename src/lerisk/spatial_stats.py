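"""Spatial autocorrelation of per-cell risk: global and local Moran's I.

Weights are contiguity (rook / queen) over the sample grid's row-column
lattice, or a distance band over cell centers.  Inference is by permutation:
full random relabeling for the global statistic, conditional permutation
(hold cell i fixed, permute the remaining values onto its neighbors) for the
local statistics.  Local clusters are labeled HH / LL / HL / LH from the
signs of the centered value and its spatial lag, masked at the chosen
pseudo-significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, spatial

from .landcover import SampleGrid

__all__ = [
    "SpatialWeights",
    "build_weights",
    "GlobalMoran",
    "global_moran",
    "LocalMoran",
    "local_moran",
]


@dataclass
class SpatialWeights:
    """Sparse spatial weights over sample-grid cells.

    ``W`` is the weight matrix actually used by the statistics (row
    standardized when requested); ``binary`` keeps the 0/1 support.
    Isolated cells (no neighbors) are flagged, not dropped.
    """

    ids: np.ndarray
    W: sparse.csr_matrix
    binary: sparse.csr_matrix
    scheme: str
    row_standardized: bool
    islands: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    def neighbor_counts(self) -> np.ndarray:
        return np.asarray((self.binary > 0).sum(axis=1)).ravel()


def build_weights(
    grid: SampleGrid,
    scheme: str = "queen",
    row_standardize: bool = True,
    distance_band: float | None = None,
) -> SpatialWeights:
    """Build contiguity or distance-band weights over grid cells.

    rook: edge-sharing cells; queen: edge- or corner-sharing; distance-band:
    centers within ``distance_band`` map units.
    """
    cells = grid.cells
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    ids = cells["cell_id"].to_numpy()
    n = len(ids)

    if scheme in ("rook", "queen"):
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        pos = {(r, c): i for i, (r, c) in enumerate(zip(cells["row"], cells["col"]))}
        ri, ci = [], []
        for i, (r, c) in enumerate(zip(cells["row"], cells["col"])):
            for dr, dc in offsets:
                j = pos.get((r + dr, c + dc))
                if j is not None:
                    ri.append(i)
                    ci.append(j)
        binary = sparse.csr_matrix(
            (np.ones(len(ri)), (ri, ci)), shape=(n, n)
        )
    elif scheme == "distance-band":
        if distance_band is None or distance_band <= 0:
            raise ValueError("distance-band scheme requires a positive distance_band")
        xy = np.column_stack(grid.centers())
        tree = spatial.cKDTree(xy)
        pairs = tree.query_pairs(distance_band, output_type="ndarray")
        if len(pairs) == 0:
            binary = sparse.csr_matrix((n, n))
        else:
            ri = np.concatenate([pairs[:, 0], pairs[:, 1]])
            ci = np.concatenate([pairs[:, 1], pairs[:, 0]])
            binary = sparse.csr_matrix((np.ones(len(ri)), (ri, ci)), shape=(n, n))
    else:
        raise ValueError(f"unknown weights scheme: {scheme!r}")

    binary.setdiag(0)
    binary.eliminate_zeros()
    deg = np.asarray(binary.sum(axis=1)).ravel()
    islands = [int(ids[i]) for i in np.flatnonzero(deg == 0)]
    if row_standardize:
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        W = sparse.diags(inv) @ binary
    else:
        W = binary.copy()
    return SpatialWeights(ids, W.tocsr(), binary.tocsr(), scheme, row_standardize, islands)


def _center(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, float)
    if np.var(x) == 0:
        raise ValueError("values have zero variance: Moran's I undefined")
    return x - x.mean()


@dataclass
class GlobalMoran:
    I: float
    expected: float
    p_sim: float
    sims: np.ndarray
    n: int
    s0: float


def global_moran(
    values,
    w: SpatialWeights,
    permutations: int = 999,
    seed: int | None = None,
) -> GlobalMoran:
    """Global Moran's I with permutation inference.

    I = (n / S0) * z' W z / z' z  with z the mean-centered values.  The
    two-sided pseudo-p compares |I*| of full random relabelings with |I|.
    """
    z = _center(values)
    n = len(z)
    if n != w.n:
        raise ValueError("values not aligned with weights")
    s0 = w.s0
    denom = float(z @ z)

    def stat(zz):
        return n / s0 * float(zz @ (w.W @ zz)) / denom

    I = stat(z)
    sims = np.empty(0)
    p = np.nan
    if permutations:
        rng = np.random.default_rng(seed)
        sims = np.array([stat(rng.permutation(z)) for _ in range(permutations)])
        p = (np.count_nonzero(np.abs(sims) >= abs(I)) + 1) / (permutations + 1)
    return GlobalMoran(I, -1.0 / (n - 1), p, sims, n, s0)


@dataclass
class LocalMoran:
    """Local Moran's I (LISA) results, one row per cell.

    ``table`` columns: cell_id, local_I, lag, p_sim, label (HH/LL/HL/LH/ns).
    """

    table: pd.DataFrame
    alpha: float
    permutations: int

    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def local_moran(
    values,
    w: SpatialWeights,
    permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> LocalMoran:
    """Local Moran's I with conditional permutation pseudo-p values.

    I_i = (z_i / m2) * sum_j w_ij z_j,  m2 = sum(z^2) / n.  For each cell the
    remaining n-1 values are randomly reassigned to its neighbor positions
    ``permutations`` times; the two-sided pseudo-p counts replicates with
    |I_i*| >= |I_i|.  Labels: HH (z>0, lag>0), LL (both < 0), HL / LH
    otherwise; cells with pseudo-p above ``alpha`` are 'ns'.
    """
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    z = _center(values)
    n = len(z)
    if n != w.n:
        raise ValueError("values not aligned with weights")
    m2 = float(z @ z) / n
    lag = w.W @ z
    local_i = z / m2 * lag

    rng = np.random.default_rng(seed)
    W = w.W
    p_sim = np.ones(n)
    for i in range(n):
        row = W.getrow(i)
        k = row.nnz
        if k == 0:
            continue
        wts = row.data
        others = np.delete(z, i)
        # uniform random k-subsets of the other n-1 values, one per replicate
        u = rng.random((permutations, n - 1))
        pick = np.argpartition(u, k - 1, axis=1)[:, :k]
        sim = z[i] / m2 * (others[pick] @ wts)
        p_sim[i] = (np.count_nonzero(np.abs(sim) >= abs(local_i[i])) + 1) / (permutations + 1)

    p_eff = _bh_adjust(p_sim) if fdr else p_sim
    label = np.where(
        p_eff <= alpha,
        np.where(z > 0, np.where(lag > 0, "HH", "HL"), np.where(lag > 0, "LH", "LL")),
        "ns",
    )
    table = pd.DataFrame(
        {
            "cell_id": w.ids,
            "local_I": local_i,
            "lag": lag,
            "p_sim": p_sim,
            "label": label,
        }
    )
    return LocalMoran(table, alpha, permutations)
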