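"""Patch delineation: per grid-cell, per-class patch count, area and perimeter.

A patch is a maximal connected component of equal-coded pixels *within* a
sample-grid cell: patches are clipped at cell boundaries, so a region
spanning two cells is counted in both.  Perimeter is the total length of
pixel edges between a class pixel and anything else — a different class,
nodata, or the cell boundary itself.  Nodata pixels contribute boundary but
never area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .landcover import LandCoverRaster, SampleGrid

__all__ = ["PatchTable", "label_patches", "per_cell_totals"]


@dataclass
class PatchTable:
    """Per-cell, per-class patch statistics plus per-cell totals.

    ``per_class`` columns: cell_id, class_code, class_name, n_patches,
    area_km2, perimeter_km.  ``totals`` columns: cell_id, n_tot, area_km2,
    perimeter_km (the denominators of the dominance index).
    """

    per_class: pd.DataFrame
    totals: pd.DataFrame
    connectivity: int

    def merged(self) -> pd.DataFrame:
        """Per-class rows joined with their cell totals (suffix ``_tot``)."""
        t = self.totals.rename(
            columns={"n_tot": "n_tot", "area_km2": "area_tot_km2", "perimeter_km": "perim_tot_km"}
        )
        return self.per_class.merge(t, on="cell_id", how="left")

    def to_csv(self, path) -> None:
        self.per_class.rename(
            columns={"n_patches": "n", "perimeter_km": "perimeter_km"}
        ).to_csv(path, index=False)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def mask_perimeter_edges(mask: np.ndarray) -> int:
    """Count boundary edges of a boolean mask (outer array edge counts too)."""
    pm = np.pad(mask, 1, constant_values=False)
    return int((pm[1:, :] != pm[:-1, :]).sum() + (pm[:, 1:] != pm[:, :-1]).sum())


def label_patches(
    raster: LandCoverRaster,
    grid: SampleGrid,
    connectivity: int = 8,
) -> PatchTable:
    """Delineate patches within every sample-grid cell.

    Area is pixel count × pixel area (km²); perimeter is boundary edge count
    × pixel edge length (km), with cell boundaries and nodata pixels both
    counting as boundary.
    """
    if grid.cell_index.shape != raster.shape:
        raise ValueError("grid and raster are inconsistent")
    struct = _structure(connectivity)
    px_area = raster.pixel_area_km2
    px_len = raster.cell_size / 1000.0

    # bounding box of each cell's pixels, for cheap per-cell slicing
    boxes = ndimage.find_objects(grid.cell_index + 1)
    rows = []
    for cid in grid.cells["cell_id"].to_numpy():
        box = boxes[cid]
        sub = raster.values[box]
        in_cell = grid.cell_index[box] == cid
        vals = sub[in_cell & (sub != raster.nodata)]
        for code in np.unique(vals):
            mask = in_cell & (sub == code)
            _, n = ndimage.label(mask, structure=struct)
            npix = int(np.count_nonzero(mask))
            rows.append(
                {
                    "cell_id": int(cid),
                    "class_code": int(code),
                    "class_name": raster.class_map[int(code)],
                    "n_patches": int(n),
                    "area_km2": npix * px_area,
                    "perimeter_km": mask_perimeter_edges(mask) * px_len,
                }
            )
    per_class = pd.DataFrame(
        rows,
        columns=["cell_id", "class_code", "class_name", "n_patches", "area_km2", "perimeter_km"],
    )
    return PatchTable(per_class, per_cell_totals(per_class), connectivity)


def per_cell_totals(per_class: pd.DataFrame) -> pd.DataFrame:
    """Sum patch counts, areas and perimeters over classes within each cell."""
    g = per_class.groupby("cell_id", as_index=False).agg(
        n_tot=("n_patches", "sum"),
        area_km2=("area_km2", "sum"),
        perimeter_km=("perimeter_km", "sum"),
    )
    return g
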