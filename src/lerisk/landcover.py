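"""Categorical land-cover rasters, the sample-grid partition, and change tabulation.

A :class:`LandCoverRaster` is a single-band integer lattice in a projected
coordinate system (meters).  Pixel (row ``r``, col ``c``) covers the half-open
square ``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` where
``(x0, y0)`` is the top-left corner and ``s`` the pixel edge length: row
indices increase southward, as in every GIS raster convention.

The risk assessment is evaluated on a :class:`SampleGrid` — a partition of the
raster into square cells (default 2.5 km) anchored at the raster origin.
Partial border cells are retained with their true valid area; cells containing
no valid pixel are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLASS_MAP",
    "LandCoverRaster",
    "SampleGrid",
    "ChangeTable",
    "read_raster",
    "write_raster",
    "build_grid",
    "tabulate_change",
]

#: Default code -> class-name mapping for the five arid-land cover classes.
DEFAULT_CLASS_MAP: dict[int, str] = {
    1: "cropland",
    2: "impervious",
    3: "grassland",
    4: "water",
    5: "wasteland",
}

# GeoTIFF tag ids used for georeferencing (ModelPixelScale, ModelTiepoint)
# and the GDAL nodata convention.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class LandCoverRaster:
    """A categorical land-cover raster in projected meters.

    Parameters
    ----------
    values : 2-D integer array of class codes (nodata included).
    cell_size : pixel edge length in meters.
    origin : (x, y) of the raster's top-left corner in projected meters.
    nodata : integer nodata code.
    class_map : mapping from code to class name.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: int = -9999
    class_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster must be a 2-D lattice with >=1 row and column")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(f"raster values must be integer, got {self.values.dtype}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.validate_codes()

    def validate_codes(self) -> None:
        codes = np.unique(self.values)
        known = set(self.class_map) | {self.nodata}
        unknown = sorted(int(c) for c in codes if int(c) not in known)
        if unknown:
            raise ValueError(f"raster contains codes outside class_map: {unknown}")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata pixels."""
        return self.values != self.nodata

    @property
    def pixel_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate 1-D arrays of column / row pixel centers (meters)."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return xs, ys

    def class_areas_km2(self) -> pd.Series:
        """Area of every class present, km², indexed by class name."""
        out = {}
        for code, name in self.class_map.items():
            n = int(np.count_nonzero(self.values == code))
            out[name] = n * self.pixel_area_km2
        return pd.Series(out, name="area_km2")

    def codes_for(self, names: Sequence[str]) -> list[int]:
        rev = {v: k for k, v in self.class_map.items()}
        return [rev[n] for n in names]


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and single-band integer GeoTIFF
# ---------------------------------------------------------------------------

def read_raster(path: str | os.PathLike, class_map: Mapping[int, str] | None = None) -> LandCoverRaster:
    """Read a single-band integer raster (ESRI ASCII ``.asc``/``.txt`` or GeoTIFF).

    Unknown class codes raise a :class:`ValueError` naming them.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if class_map is None:
        class_map = dict(DEFAULT_CLASS_MAP)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".txt"):
        return _read_ascii(path, class_map)
    if ext in (".tif", ".tiff"):
        return _read_geotiff(path, class_map)
    raise ValueError(f"unsupported raster format: {ext!r}")


def write_raster(raster: LandCoverRaster, path: str | os.PathLike) -> None:
    """Write a raster as ESRI ASCII grid or GeoTIFF, chosen by extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".txt"):
        _write_ascii(raster, path)
    elif ext in (".tif", ".tiff"):
        _write_geotiff(raster, path)
    else:
        raise ValueError(f"unsupported raster format: {ext!r}")


def _read_ascii(path: str, class_map: Mapping[int, str]) -> LandCoverRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    s = header["cellsize"]
    data = np.asarray(data).reshape(nrows, ncols)
    if not np.allclose(data, np.round(data)):
        raise ValueError("raster band is not integer-valued")
    values = np.round(data).astype(np.int32)
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        xll, yll = header["xllcenter"] - s / 2, header["yllcenter"] - s / 2
    origin = (xll, yll + nrows * s)
    nodata = int(header.get("nodata_value", -9999))
    return LandCoverRaster(values, s, origin, nodata, dict(class_map))


def _write_ascii(raster: LandCoverRaster, path: str) -> None:
    nr, nc = raster.shape
    x0, y0 = raster.origin
    s = raster.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {y0 - nr * s:.6f}\n")
        fh.write(f"cellsize {s:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.values, fmt="%d")


def _read_geotiff(path: str, class_map: Mapping[int, str]) -> LandCoverRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = -9999
        if _TAG_GDAL_NODATA in tags:
            nodata = int(float(tags[_TAG_GDAL_NODATA].value))
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("GeoTIFF band is not integer-valued")
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError("only square pixels are supported")
    # tiepoint maps raster (i, j, k) -> model (x, y, z); anchored at (0, 0)
    origin = (float(tie[3]), float(tie[4]))
    return LandCoverRaster(values.astype(np.int32), float(scale[0]), origin, nodata, dict(class_map))


def _write_geotiff(raster: LandCoverRaster, path: str) -> None:
    import tifffile

    s = float(raster.cell_size)
    x0, y0 = (float(v) for v in raster.origin)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(path, raster.values.astype(np.int32), extratags=extratags)


# ---------------------------------------------------------------------------
# Sample grid
# ---------------------------------------------------------------------------

@dataclass
class SampleGrid:
    """Partition of a raster into square evaluation cells.

    ``cells`` has one row per retained cell: ``cell_id`` (dense integer),
    ``row``/``col`` (grid coordinates), ``x``/``y`` (geometric center of the
    full, unclipped grid square — the point support of the per-cell risk
    index), and ``valid_area_km2``.  ``cell_index`` maps every raster pixel to
    the dense cell id (−1 for pixels in dropped cells).
    """

    cell_size_m: float
    cells: pd.DataFrame
    cell_index: np.ndarray
    n_cell_rows: int
    n_cell_cols: int
    raster_cell_size: float
    origin: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.cells["x"].to_numpy(), self.cells["y"].to_numpy()


def build_grid(
    raster: LandCoverRaster,
    cell_size_m: float = 2500.0,
    offset: tuple[float, float] = (0.0, 0.0),
) -> SampleGrid:
    """Partition ``raster`` into square sample cells of edge ``cell_size_m``.

    The grid is anchored at the raster's top-left origin (optionally shifted
    by ``offset`` in map units).  Pixels are assigned to the cell containing
    their center.  Border cells keep their true valid area; all-nodata cells
    are dropped.
    """
    if cell_size_m < raster.cell_size:
        raise ValueError(
            f"grid cell ({cell_size_m} m) must be at least one pixel ({raster.cell_size} m)"
        )
    nr, nc = raster.shape
    s, g = raster.cell_size, float(cell_size_m)
    ax = raster.origin[0] + offset[0]
    ay = raster.origin[1] + offset[1]

    xs, ys = raster.pixel_centers()
    ccol = np.floor((xs - ax) / g).astype(np.int64)
    crow = np.floor((ay - ys) / g).astype(np.int64)
    ccol -= ccol.min()
    crow -= crow.min()
    n_rows, n_cols = int(crow.max()) + 1, int(ccol.max()) + 1

    dense = crow[:, None] * n_cols + ccol[None, :]
    valid = raster.valid
    counts = np.bincount(dense[valid].ravel(), minlength=n_rows * n_cols)
    keep = np.flatnonzero(counts > 0)
    remap = np.full(n_rows * n_cols, -1, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    cell_index = remap[dense]

    rows, cols = np.divmod(keep, n_cols)
    px_area = raster.pixel_area_km2
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(keep)),
            "row": rows,
            "col": cols,
            "x": ax + (cols + 0.5) * g,
            "y": ay - (rows + 0.5) * g,
            "valid_area_km2": counts[keep] * px_area,
        }
    )
    return SampleGrid(g, cells, cell_index, n_rows, n_cols, s, raster.origin)


# ---------------------------------------------------------------------------
# Land-cover change
# ---------------------------------------------------------------------------

@dataclass
class ChangeTable:
    """Per-class areas by epoch and from→to transition matrices (km²)."""

    areas: pd.DataFrame            # index: epoch label, columns: class names
    changes: pd.DataFrame          # epoch_start, epoch_end, class, area_start, area_end, delta
    transitions: dict[tuple[str, str], pd.DataFrame]

    def to_csv(self, path: str | os.PathLike) -> None:
        self.changes.to_csv(path, index=False)


def tabulate_change(
    rasters: Sequence[LandCoverRaster],
    labels: Sequence[str] | None = None,
) -> ChangeTable:
    """Tabulate per-class areas and pixel transitions over an ordered raster sequence.

    Rasters must share shape, origin and cell size (co-registered epochs).
    Transition matrices count only pixels valid in both epochs.
    """
    if len(rasters) < 1:
        raise ValueError("need at least one raster")
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape or r.cell_size != ref.cell_size or r.origin != ref.origin:
            raise ValueError("rasters are not co-registered (shape/origin/cell size mismatch)")
    if labels is None:
        labels = [f"epoch{i}" for i in range(len(rasters))]

    names = [ref.class_map[c] for c in sorted(ref.class_map)]
    areas = pd.DataFrame(
        {lab: r.class_areas_km2() for lab, r in zip(labels, rasters)}
    ).T.reindex(columns=names)
    areas.index.name = "epoch"

    px = ref.pixel_area_km2
    rows = []
    transitions: dict[tuple[str, str], pd.DataFrame] = {}
    for (la, ra), (lb, rb) in zip(zip(labels, rasters), zip(labels[1:], rasters[1:])):
        both = ra.valid & rb.valid
        codes = sorted(ref.class_map)
        mat = np.zeros((len(codes), len(codes)))
        a, b = ra.values[both], rb.values[both]
        for i, ca in enumerate(codes):
            sel = a == ca
            if not sel.any():
                continue
            mat[i, :] = np.bincount(
                np.searchsorted(codes, b[sel]), minlength=len(codes)
            ) * px
        tm = pd.DataFrame(mat, index=names, columns=names)
        transitions[(la, lb)] = tm
        for name in names:
            a0, a1 = areas.loc[la, name], areas.loc[lb, name]
            rows.append(
                {
                    "epoch_start": la,
                    "epoch_end": lb,
                    "class": name,
                    "area_start_km2": a0,
                    "area_end_km2": a1,
                    "delta_km2": a1 - a0,
                }
            )
    changes = pd.DataFrame(
        rows,
        columns=["epoch_start", "epoch_end", "class", "area_start_km2", "area_end_km2", "delta_km2"],
    )
    return ChangeTable(areas, changes, transitions)
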