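"""Geographically weighted regression of risk on distance covariates.

The driving covariates are per-cell Euclidean distances from each grid-cell
center to the nearest water pixel and to the nearest impervious (built-up)
pixel.  GWR fits a weighted least-squares regression at every cell, with
kernel weights decaying over distance between cells, so the coefficients
(the local influence of proximity to water or settlements on ecological
risk) vary across the landscape.  Bandwidth can be fixed or selected by
minimizing the corrected Akaike criterion (AICc) with golden-section search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import spatial

from .landcover import LandCoverRaster, SampleGrid

__all__ = [
    "distance_to_class",
    "GWRFit",
    "fit_gwr",
    "coefficient_maps",
]


def distance_to_class(
    raster: LandCoverRaster,
    grid: SampleGrid,
    target: str,
) -> pd.DataFrame:
    """Exact Euclidean distance (km) from each cell center to the nearest
    pixel center of the target class.

    Zero iff the center lies on a pixel of the target class.  Raises if the
    class is absent from the raster.
    """
    rev = {v: k for k, v in raster.class_map.items()}
    if target not in rev:
        raise ValueError(f"unknown class: {target!r}")
    code = rev[target]
    mask = raster.values == code
    if not mask.any():
        raise ValueError(f"class absent: {target}")
    xs, ys = raster.pixel_centers()
    rr, cc = np.nonzero(mask)
    tree = spatial.cKDTree(np.column_stack([xs[cc], ys[rr]]))
    centers = np.column_stack(grid.centers())
    d, _ = tree.query(centers)
    return pd.DataFrame(
        {"cell_id": grid.cells["cell_id"].to_numpy(), f"d_{target}_km": d / 1000.0}
    )


def _kernel_weights(d: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return np.exp(-0.5 * (d / bandwidth) ** 2)
    if kernel == "bisquare":
        u = d / bandwidth
        return np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    raise ValueError(f"unknown kernel: {kernel!r}")


@dataclass
class GWRFit:
    """A fitted geographically weighted regression.

    ``params``: one row per location — intercept and slope(s), fitted value,
    residual, and the location's hat-matrix diagonal entry.
    """

    params: pd.DataFrame
    names: list[str]
    kernel: str
    bandwidth: float
    aicc: float
    r2: float
    tr_s: float
    n: int
    ridge_locations: int = 0

    def coefficients(self, name: str) -> np.ndarray:
        return self.params[f"beta_{name}"].to_numpy()


def _gwr_solve(
    xy: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    bandwidth: float,
    kernel: str,
):
    """Local WLS at every observation; returns betas, hat diag, ridge count."""
    n, p = X.shape
    betas = np.empty((n, p))
    s_diag = np.empty(n)
    n_ridge = 0
    d_all = spatial.distance.cdist(xy, xy)
    for i in range(n):
        w = _kernel_weights(d_all[i], bandwidth, kernel)
        xtw = X.T * w
        xtwx = xtw @ X
        xtwy = xtw @ y
        try:
            beta = np.linalg.solve(xtwx, xtwy)
            hvec = np.linalg.solve(xtwx, X[i] * w[i])
        except np.linalg.LinAlgError:
            n_ridge += 1
            lam = 1e-8 * max(np.trace(xtwx), 1.0)
            xtwx_r = xtwx + lam * np.eye(p)
            beta = np.linalg.solve(xtwx_r, xtwy)
            hvec = np.linalg.solve(xtwx_r, X[i] * w[i])
        betas[i] = beta
        s_diag[i] = X[i] @ hvec
    return betas, s_diag, n_ridge


def _aicc(y: np.ndarray, yhat: np.ndarray, tr_s: float) -> float:
    n = len(y)
    rss = float(np.sum((y - yhat) ** 2))
    if rss <= 0:
        return -np.inf
    denom = n - 2.0 - tr_s
    if denom <= 0:
        return np.inf
    return n * math.log(rss / n) + n * math.log(2 * math.pi) + n * (n + tr_s) / denom


def fit_gwr(
    x: np.ndarray,
    y: np.ndarray,
    response: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    kernel: str = "gaussian",
    bandwidth: float | str = "select",
) -> GWRFit:
    """Fit a GWR of ``response`` on ``covariates`` at locations (x, y).

    ``bandwidth`` is in map units (meters for projected grids); ``"select"``
    minimizes AICc over bandwidth by golden-section search.  Locations with
    a singular local design fall back to a tiny ridge penalty (with a
    warning counted in ``ridge_locations``).
    """
    xy = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    yv = np.asarray(response, float)
    if isinstance(covariates, pd.DataFrame):
        names = [c.removeprefix("d_").removesuffix("_km") for c in covariates.columns]
        Xc = covariates.to_numpy(float)
    else:
        Xc = np.atleast_2d(np.asarray(covariates, float))
        if Xc.shape[0] != len(yv):
            Xc = Xc.T
        names = [f"x{i}" for i in range(Xc.shape[1])]
    n, p = len(yv), Xc.shape[1] + 1
    if n < 3 + Xc.shape[1]:
        raise ValueError("too few points for GWR")
    X = np.column_stack([np.ones(n), Xc])

    if bandwidth == "select":
        dmax = float(np.ptp(xy[:, 0]) + np.ptp(xy[:, 1])) or 1.0
        lo, hi = math.log(dmax * 0.02), math.log(dmax * 4.0)
        phi = (math.sqrt(5) - 1) / 2

        def score(logbw):
            b, s, _ = _gwr_solve(xy, X, yv, math.exp(logbw), kernel)
            return _aicc(yv, np.einsum("ij,ij->i", X, b), float(s.sum()))

        a, b_ = lo, hi
        c1, c2 = b_ - phi * (b_ - a), a + phi * (b_ - a)
        f1, f2 = score(c1), score(c2)
        for _ in range(30):
            if f1 <= f2:
                b_, c2, f2 = c2, c1, f1
                c1 = b_ - phi * (b_ - a)
                f1 = score(c1)
            else:
                a, c1, f1 = c1, c2, f2
                c2 = a + phi * (b_ - a)
                f2 = score(c2)
        bw = math.exp((a + b_) / 2)
    else:
        bw = float(bandwidth)

    betas, s_diag, n_ridge = _gwr_solve(xy, X, yv, bw, kernel)
    if n_ridge:
        warnings.warn(f"singular local design at {n_ridge} locations; ridge fallback used")
    yhat = np.einsum("ij,ij->i", X, betas)
    resid = yv - yhat
    tr_s = float(s_diag.sum())
    tss = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan

    cols = {"x": xy[:, 0], "y": xy[:, 1], "beta_intercept": betas[:, 0]}
    for j, nm in enumerate(names):
        cols[f"beta_{nm}"] = betas[:, j + 1]
    cols.update({"fitted": yhat, "residual": resid, "hat": s_diag})
    return GWRFit(
        pd.DataFrame(cols), ["intercept"] + names, kernel, bw,
        _aicc(yv, yhat, tr_s), r2, tr_s, n, n_ridge,
    )


def coefficient_maps(fit: GWRFit, grid: SampleGrid) -> dict[str, np.ndarray]:
    """Rasterize local coefficients onto the sample-grid lattice.

    Returns one (n_cell_rows x n_cell_cols) float array per coefficient,
    NaN where no cell exists.  Row order of ``fit.params`` must align with
    ``grid.cells`` (the pipeline guarantees this).
    """
    out = {}
    rows = grid.cells["row"].to_numpy()
    cols = grid.cells["col"].to_numpy()
    for nm in fit.names:
        arr = np.full((grid.n_cell_rows, grid.n_cell_cols), np.nan)
        arr[rows, cols] = fit.params[f"beta_{nm}"].to_numpy()
        out[nm] = arr
    return out
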