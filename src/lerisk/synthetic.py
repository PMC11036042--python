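"""Synthetic land-cover generators.

Two generators:

* :func:`neutral_landscape` — a neutral model (spatially filtered Gaussian
  noise thresholded at class-proportion quantiles) with controllable class
  shares and fragmentation, for unit tests and calibration.
* :func:`oasis_scenario` — a stylized desert-basin landscape: a wasteland
  (desert) matrix crossed by a sinuous river corridor ending in a shallow
  terminal lake, a grassland halo hugging the water, compact cropland
  patches, and small impervious (town) seeds.  Default composition follows
  an arid endorheic basin: desert well above 80% of the area, grassland
  around 8%, water on the order of 1%, cropland and settlements below 1%.

:func:`conveyance_series` grows the water corridor and lake monotonically
across epochs — the signature of engineered ecological water conveyance —
holding everything else fixed, and returns per-epoch ground truth for
assertions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point

from .landcover import DEFAULT_CLASS_MAP, LandCoverRaster

__all__ = ["ScenarioConfig", "neutral_landscape", "oasis_scenario", "conveyance_series"]

_CODE = {v: k for k, v in DEFAULT_CLASS_MAP.items()}


def neutral_landscape(
    shape: tuple[int, int],
    proportions: dict[str, float],
    smoothing_scale: float = 4.0,
    seed: int = 0,
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandCoverRaster:
    """Neutral land-cover model with target class shares.

    A Gaussian-filtered white-noise field is thresholded at the cumulative
    proportion quantiles, so realized shares match the targets up to
    discretization; larger ``smoothing_scale`` (pixels) yields fewer, larger
    patches.  Any share not assigned goes to wasteland.
    """
    props = dict(proportions)
    bad = [k for k, v in props.items() if not (0.0 <= v <= 1.0)]
    if bad or sum(props.values()) > 1.0 + 1e-9:
        raise ValueError(f"proportions must lie in [0,1] and sum to <= 1: {props}")
    rest = 1.0 - sum(props.values())
    if rest > 1e-9:
        props["wasteland"] = props.get("wasteland", 0.0) + rest

    rng = np.random.default_rng(seed)
    fld = rng.standard_normal(shape)
    if smoothing_scale > 0:
        fld = ndimage.gaussian_filter(fld, smoothing_scale)

    names = [n for n in props if props[n] > 0]
    shares = np.array([props[n] for n in names])
    qs = np.cumsum(shares)[:-1]
    cuts = np.quantile(fld, qs) if len(qs) else np.empty(0)
    idx = np.digitize(fld, cuts)
    values = np.zeros(shape, dtype=np.int32)
    for i, n in enumerate(names):
        values[idx == i] = _CODE[n]
    return LandCoverRaster(values, cell_size, origin)


@dataclass
class ScenarioConfig:
    """Geometry and composition of the desert–river–oasis scenario.

    Distances are km within a domain anchored at ``origin`` (projected
    meters, top-left).  ``roughness_km`` perturbs the painted boundaries
    with a smooth noise field (same field for every epoch of a series, so
    growing geometry nests monotonically); set 0 for exact geometry.
    """

    shape: tuple[int, int] = (250, 250)
    cell_size: float = 200.0                      # m per pixel -> 50 x 50 km
    origin: tuple[float, float] = (0.0, 50_000.0)
    seed: int = 0
    river_points_km: tuple[tuple[float, float], ...] = (
        (0.0, 31.0), (9.0, 35.0), (18.0, 29.5), (28.0, 34.0), (36.0, 32.5),
    )
    corridor_width_km: float = 0.5
    lake_center_km: tuple[float, float] = (41.0, 33.0)
    lake_radius_km: float = 2.0
    halo_width_km: float = 2.0
    cropland_sites_km: tuple[tuple[float, float, float], ...] = (
        (8.0, 28.5, 1.6), (16.5, 26.5, 1.3), (24.0, 37.5, 1.2),
    )
    town_sites_km: tuple[tuple[float, float, float], ...] = (
        (8.6, 26.3, 0.55), (22.5, 38.6, 0.45),
    )
    roughness_km: float = 0.0
    roughness_scale_px: float = 6.0

    def domain_km(self) -> tuple[float, float]:
        nr, nc = self.shape
        return nc * self.cell_size / 1000.0, nr * self.cell_size / 1000.0


def _pixel_grid_km(cfg: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in km relative to the domain's lower-left."""
    nr, nc = cfg.shape
    s = cfg.cell_size / 1000.0
    x = (np.arange(nc) + 0.5) * s
    y_top_down = (np.arange(nr) + 0.5) * s
    _, h = cfg.domain_km()
    y = h - y_top_down  # row 0 is the top
    return np.meshgrid(x, y)


def _noise_fields(cfg: ScenarioConfig, n: int) -> list[np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(n):
        f = ndimage.gaussian_filter(rng.standard_normal(cfg.shape), cfg.roughness_scale_px)
        sd = f.std()
        out.append(f / sd if sd > 0 else f)
    return out


def _paint(cfg: ScenarioConfig, noise: list[np.ndarray], width_km: float, lake_radius_km: float):
    """Paint one epoch; returns (values, truth dict)."""
    X, Y = _pixel_grid_km(cfg)
    line = LineString(cfg.river_points_km + (cfg.lake_center_km,))
    if line.length == 0:
        raise ValueError("degenerate geometry: zero-length river centerline")
    pts = shapely.points(X.ravel(), Y.ravel())
    d_line = shapely.distance(pts, line).reshape(cfg.shape)
    d_lake = np.hypot(X - cfg.lake_center_km[0], Y - cfg.lake_center_km[1])

    r = cfg.roughness_km
    corridor = d_line + r * noise[0] <= width_km / 2.0
    lake = d_lake + r * noise[0] <= lake_radius_km
    water = corridor | lake

    values = np.full(cfg.shape, _CODE["wasteland"], dtype=np.int32)
    values[water] = _CODE["water"]

    # grassland halo: within halo_width of water, perturbed, excluding water
    if water.any() and cfg.halo_width_km > 0:
        px_km = cfg.cell_size / 1000.0
        d_water = ndimage.distance_transform_edt(~water) * px_km
        halo = (d_water + r * noise[1] <= cfg.halo_width_km) & ~water
    else:
        halo = np.zeros(cfg.shape, dtype=bool)
    values[halo] = _CODE["grassland"]

    for cx, cy, rad in cfg.cropland_sites_km:
        blob = np.hypot(X - cx, Y - cy) + r * noise[2] <= rad
        values[blob] = _CODE["cropland"]
    for cx, cy, half in cfg.town_sites_km:
        sq = (np.abs(X - cx) <= half) & (np.abs(Y - cy) <= half)
        values[sq] = _CODE["impervious"]

    px_area = (cfg.cell_size / 1000.0) ** 2
    lake_geom = Point(cfg.lake_center_km).buffer(lake_radius_km, quad_segs=64)
    water_geom = line.buffer(width_km / 2.0, quad_segs=64).union(lake_geom) if width_km > 0 else lake_geom
    truth = {
        "water_mask": values == _CODE["water"],
        "grassland_mask": values == _CODE["grassland"],
        "cropland_mask": values == _CODE["cropland"],
        "impervious_mask": values == _CODE["impervious"],
        "wasteland_mask": values == _CODE["wasteland"],
        "river_line_km": line,
        "water_geom_km": water_geom,
        "analytic_water_area_km2": water_geom.area if (width_km > 0 or lake_radius_km > 0) else 0.0,
        "class_areas_km2": {
            name: float(np.count_nonzero(values == code) * px_area)
            for code, name in DEFAULT_CLASS_MAP.items()
        },
        "corridor_width_km": width_km,
        "lake_radius_km": lake_radius_km,
    }
    return values, truth


def oasis_scenario(config: ScenarioConfig | None = None):
    """Generate the desert–river–oasis landscape.

    Returns ``(raster, truth)`` where ``truth`` carries per-class masks, the
    analytic water geometry (buffered centerline plus lake disc) and painted
    class areas for use as test ground truth.
    """
    cfg = config or ScenarioConfig()
    noise = _noise_fields(cfg, 3)
    values, truth = _paint(cfg, noise, cfg.corridor_width_km, cfg.lake_radius_km)
    raster = LandCoverRaster(values, cfg.cell_size, cfg.origin)
    return raster, truth


def conveyance_series(
    config: ScenarioConfig | None = None,
    epochs: int = 4,
    corridor_growth_km: float = 0.25,
    lake_growth_km: float = 0.4,
) -> tuple[list[LandCoverRaster], list[dict]]:
    """A monotone water-conveyance sequence of landscapes.

    Epoch ``e`` has corridor width ``w0 + e*corridor_growth`` and lake radius
    ``r0 + e*lake_growth``; the grassland halo tracks the widening water.
    The boundary-roughness noise fields are generated once, so water and
    halo masks nest across epochs.
    """
    if epochs < 2:
        raise ValueError("need at least 2 epochs")
    cfg = config or ScenarioConfig()
    noise = _noise_fields(cfg, 3)
    rasters, truths = [], []
    for e in range(epochs):
        w = cfg.corridor_width_km + e * corridor_growth_km
        rl = cfg.lake_radius_km + e * lake_growth_km
        values, truth = _paint(cfg, noise, w, rl)
        rasters.append(LandCoverRaster(values, cfg.cell_size, cfg.origin))
        truths.append(truth)
    return rasters, truths
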