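"""Continuous risk surface: ordinary kriging and natural-breaks classification.

The per-cell ERI values are point data at grid-cell centers.  This module
fits an empirical semivariogram, interpolates the points to a raster lattice
by ordinary kriging (unbiasedness constraint: weights sum to one), and
classifies the surface into five ordered risk levels with Jenks natural
breaks (Fisher's optimal-partition dynamic program).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, spatial

__all__ = [
    "VariogramModel",
    "fit_variogram",
    "krige",
    "jenks_breaks",
    "RiskSurface",
    "classify_and_tabulate",
    "RISK_LABELS",
]

RISK_LABELS = ["very low", "low", "moderate", "high", "very high"]


@dataclass
class VariogramModel:
    """A fitted isotropic semivariogram.

    ``sill`` is the total sill (nugget + partial sill); ``gamma(h)`` is the
    model semivariance with the conventional discontinuity gamma(0) = 0.
    """

    family: str
    nugget: float
    sill: float
    range_: float
    lags: np.ndarray | None = None          # bin center distances
    semivariances: np.ndarray | None = None
    pair_counts: np.ndarray | None = None

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    def gamma(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        c0, c1, r = self.nugget, self.partial_sill, self.range_
        hr = h / r
        if self.family == "spherical":
            g = np.where(hr < 1.0, c1 * (1.5 * hr - 0.5 * hr**3), c1)
        elif self.family == "exponential":
            g = c1 * (1.0 - np.exp(-3.0 * hr))
        elif self.family == "gaussian":
            g = c1 * (1.0 - np.exp(-3.0 * hr**2))
        else:
            raise ValueError(f"unknown variogram family: {self.family}")
        return np.where(h > 0, c0 + g, 0.0)


def empirical_variogram(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    n_lags: int = 12,
    max_dist: float | None = None,
    min_pairs: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram: mean of 0.5*(z_i - z_j)^2 per lag bin."""
    pts = np.column_stack([x, y]).astype(float)
    d = spatial.distance.pdist(pts)
    dz2 = 0.5 * spatial.distance.pdist(np.asarray(z, float)[:, None], "sqeuclidean")
    if max_dist is None:
        max_dist = 0.5 * d.max()
    edges = np.linspace(0, max_dist, n_lags + 1)
    which = np.digitize(d, edges) - 1
    sel = (which >= 0) & (which < n_lags)
    counts = np.bincount(which[sel], minlength=n_lags)
    sums = np.bincount(which[sel], weights=dz2[sel], minlength=n_lags)
    dsum = np.bincount(which[sel], weights=d[sel], minlength=n_lags)
    keep = counts >= min_pairs
    with np.errstate(invalid="ignore"):
        gam = sums[keep] / counts[keep]
        lag = dsum[keep] / counts[keep]
    return lag, gam, counts[keep]


def fit_variogram(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    family: str = "spherical",
    n_lags: int = 12,
    max_dist: float | None = None,
) -> VariogramModel:
    """Fit a variogram model to the empirical semivariogram.

    Least squares weighted by per-bin pair counts; bins with too few pairs
    are dropped.  Raises on a spatially constant field (zero variance).
    """
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    if len(z) < 10:
        raise ValueError("need at least 10 points to fit a variogram")
    if np.var(z) == 0:
        raise ValueError("all values identical: variogram undefined (zero variance)")
    lag, gam, counts = empirical_variogram(x, y, z, n_lags, max_dist)
    if len(lag) < 3:
        raise ValueError("too few usable lag bins")

    var = float(np.var(z))
    w = np.sqrt(counts.astype(float))

    def resid(p):
        m = VariogramModel(family, p[0], p[0] + p[1], p[2])
        return w * (m.gamma(lag) - gam)

    p0 = np.array([max(gam[0], 1e-12), max(var - gam[0], 1e-12), lag[-1] / 2])
    lb = np.array([0.0, 0.0, lag[0] * 1e-3])
    ub = np.array([np.inf, np.inf, np.inf])
    sol = optimize.least_squares(resid, np.clip(p0, lb + 1e-15, None), bounds=(lb, ub))
    nugget, psill, rng = sol.x
    return VariogramModel(family, float(nugget), float(nugget + psill), float(rng), lag, gam, counts)


def _merge_duplicates(x, y, z):
    df = pd.DataFrame({"x": x, "y": y, "z": z}).groupby(["x", "y"], as_index=False).mean()
    return df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy()


def krige(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    model: VariogramModel,
    x_target: np.ndarray,
    y_target: np.ndarray,
    n_neighbors: int | None = 16,
    return_weights: bool = False,
    chunk: int = 4096,
):
    """Ordinary kriging of point data onto target locations.

    For each target the (k+1)x(k+1) augmented system over the ``n_neighbors``
    nearest samples is solved with a Lagrange multiplier enforcing that the
    weights sum to one.  ``n_neighbors=None`` uses all points (exact global
    kriging; intended for <= ~2000 points).  Duplicate sample locations are
    merged (averaged) before solving.

    Returns the predicted values (flat array aligned with the targets), and
    optionally the (targets x samples-used) weight matrix of the last chunk
    when ``return_weights`` (only sensible for a single small chunk).
    """
    x, y, z = _merge_duplicates(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float))
    pts = np.column_stack([x, y])
    n = len(pts)
    k = n if n_neighbors is None else min(int(n_neighbors), n)
    tree = spatial.cKDTree(pts)
    xt = np.asarray(x_target, float).ravel()
    yt = np.asarray(y_target, float).ravel()
    targets = np.column_stack([xt, yt])

    pred = np.empty(len(targets))
    weights_out = None
    for start in range(0, len(targets), chunk):
        tg = targets[start:start + chunk]
        dist, idx = tree.query(tg, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        nb = pts[idx]                                   # (t, k, 2)
        dmat = np.linalg.norm(nb[:, :, None, :] - nb[:, None, :, :], axis=-1)
        t = len(tg)
        a = np.zeros((t, k + 1, k + 1))
        a[:, :k, :k] = model.gamma(dmat)
        a[:, k, :k] = 1.0
        a[:, :k, k] = 1.0
        b = np.zeros((t, k + 1))
        b[:, :k] = model.gamma(dist)
        b[:, k] = 1.0
        try:
            sol = np.linalg.solve(a, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack([np.linalg.lstsq(ai, bi, rcond=None)[0] for ai, bi in zip(a, b)])
        w = sol[:, :k]
        pred[start:start + chunk] = np.einsum("tk,tk->t", w, z[idx])
        if return_weights:
            weights_out = (w, idx)
    if return_weights:
        return pred, weights_out
    return pred


# ---------------------------------------------------------------------------
# Jenks natural breaks (Fisher optimal partition, dynamic programming)
# ---------------------------------------------------------------------------

def jenks_breaks(values, k: int = 5, max_n: int = 3000) -> np.ndarray:
    """Optimal natural-breaks thresholds for ``k`` contiguous classes.

    Minimizes the total within-class sum of squared deviations over all
    partitions of the sorted values (exact dynamic program).  Returns the
    ``k-1`` upper class bounds (data values); classes are right-closed:
    value <= break -> lower class.  Inputs longer than ``max_n`` are
    deterministically thinned (evenly spaced order statistics) first.
    """
    v = np.sort(np.asarray(values, float).ravel())
    v = v[np.isfinite(v)]
    if len(np.unique(v)) < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")
    if len(v) > max_n:
        v = v[np.linspace(0, len(v) - 1, max_n).round().astype(int)]
    n = len(v)
    cum = np.concatenate([[0.0], np.cumsum(v)])
    cum2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse_to(j, i):
        """Within-class SSE of v[i..j] for vector i (inclusive)."""
        cnt = j - i + 1
        s = cum[j + 1] - cum[i]
        s2 = cum2[j + 1] - cum2[i]
        return s2 - s * s / cnt

    # cost[j] = optimal SSE of v[0..j] using (c+1) classes
    cost = sse_to(np.arange(n), np.zeros(n, dtype=int))
    back = np.zeros((k, n), dtype=int)
    for c in range(1, k):
        new = np.empty(n)
        new[:c] = np.inf  # cannot split fewer points than classes
        for j in range(c, n):
            i = np.arange(c, j + 1)
            cand = cost[i - 1] + sse_to(j, i)
            m = int(np.argmin(cand))
            new[j] = cand[m]
            back[c, j] = c + m
        cost = new

    # recover class boundaries
    cuts = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        cuts.append(i - 1)  # last index of the previous class block
        j = i - 1
    cuts = sorted(cuts)
    return v[np.array(cuts)]


@dataclass
class RiskSurface:
    """An interpolated ERI surface classified into ordered risk levels."""

    values: np.ndarray            # float ERI raster
    classes: np.ndarray           # int raster 1..k (0 = invalid)
    breaks: np.ndarray            # k-1 strictly increasing thresholds
    labels: list[str]
    percentages: pd.Series        # % of valid area per class label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.labels, "percent_area": self.percentages.to_numpy()}
        )


def classify_and_tabulate(
    surface: np.ndarray,
    breaks,
    valid_mask: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> RiskSurface:
    """Apply natural-breaks thresholds to a surface and tabulate class areas.

    Intervals are right-closed: (-inf, b1], (b1, b2], ..., (b_{k-1}, inf).
    Percentages are of the valid area and sum to 100.
    """
    surface = np.asarray(surface, float)
    breaks = np.asarray(breaks, float).ravel()
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing")
    k = len(breaks) + 1
    if labels is None:
        labels = RISK_LABELS if k == 5 else [f"class {i + 1}" for i in range(k)]
    if valid_mask is None:
        valid_mask = np.isfinite(surface)
    cls = np.zeros(surface.shape, dtype=np.int32)
    cls[valid_mask] = np.digitize(surface[valid_mask], breaks, right=True) + 1
    nvalid = int(valid_mask.sum())
    if nvalid == 0:
        raise ValueError("no valid pixels to classify")
    counts = np.bincount(cls[valid_mask], minlength=k + 1)[1:]
    pct = pd.Series(100.0 * counts / nvalid, index=labels, name="percent_area")
    return RiskSurface(surface, cls, breaks, list(labels), pct)
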