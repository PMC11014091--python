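"""Arable-fraction-weighted aggregation of rasters to administrative units.

Pixels whose arable-land fraction is below a threshold (default 30 %) are
discarded.  Each surviving pixel is weighted by the product of its arable
fraction ``a`` and the fraction ``c`` of the pixel covered by the unit
polygon, then weights are normalised to sum to one per unit; the unit value
for a date is the weighted mean over non-missing pixels, with weights
renormalised over the non-missing subset (daily cloud gaps are routine and
should not void the whole unit).

Rasters are plain 2-d numpy arrays on a unit-spaced grid: pixel (row, col)
spans x in [col, col+1), y in [row, row+1) (half-open extents), so polygon
coverage fractions are shapely intersection areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

ARABLE_THRESHOLD = 0.30


@dataclass
class PixelWeightTable:
    """Per-unit surviving pixels with arable fraction, coverage and weight.

    ``table`` columns: unit_id, row, col, arable_fraction, coverage, weight.
    Weights sum to one within each unit.  ``empty_units`` lists units with
    no surviving pixel ("no data").
    """

    table: pd.DataFrame
    grid_shape: tuple[int, int]
    empty_units: tuple[str, ...] = ()

    def weights_for(self, unit_id: str) -> pd.DataFrame:
        return self.table[self.table["unit_id"] == unit_id]


def pixel_coverage_fractions(
    polygon: BaseGeometry, grid_shape: tuple[int, int]
) -> np.ndarray:
    """Fraction of each pixel's area covered by ``polygon``."""
    nrows, ncols = grid_shape
    cov = np.zeros((nrows, ncols), dtype=float)
    minx, miny, maxx, maxy = polygon.bounds
    r0, r1 = max(0, int(np.floor(miny))), min(nrows, int(np.ceil(maxy)))
    c0, c1 = max(0, int(np.floor(minx))), min(ncols, int(np.ceil(maxx)))
    for r in range(r0, r1):
        for c in range(c0, c1):
            cell = box(c, r, c + 1, r + 1)
            cov[r, c] = polygon.intersection(cell).area
    return cov


def build_weights(
    arable: np.ndarray,
    units: dict[str, BaseGeometry],
    threshold: float = ARABLE_THRESHOLD,
    *,
    coverage: dict[str, np.ndarray] | None = None,
) -> PixelWeightTable:
    """Build the normalised pixel-weight table for every unit.

    ``arable`` is the arable-fraction raster; ``units`` maps unit id to its
    polygon in the same grid frame.  Pixels with arable fraction strictly
    below ``threshold`` are excluded (exactly at the threshold survives).
    Pre-computed coverage rasters may be passed to skip the geometry step.
    """
    arable = np.asarray(arable, dtype=float)
    if np.nanmin(arable) < 0 or np.nanmax(arable) > 1:
        raise ValueError("arable fractions must lie in [0, 1]")
    rows = []
    empty = []
    for uid, poly in units.items():
        cov = (
            coverage[uid]
            if coverage is not None
            else pixel_coverage_fractions(poly, arable.shape)
        )
        if cov.shape != arable.shape:
            raise ValueError("coverage raster does not match arable raster grid")
        keep = (arable >= threshold) & (cov > 0)
        rr, cc = np.nonzero(keep)
        raw = arable[rr, cc] * cov[rr, cc]
        total = raw.sum()
        if total <= 0:
            empty.append(uid)
            continue
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": uid,
                    "row": rr,
                    "col": cc,
                    "arable_fraction": arable[rr, cc],
                    "coverage": cov[rr, cc],
                    "weight": raw / total,
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["unit_id", "row", "col", "arable_fraction", "coverage", "weight"]
        )
    )
    return PixelWeightTable(
        table=table, grid_shape=arable.shape, empty_units=tuple(empty)
    )


def aggregate_to_unit(values: np.ndarray, weights: PixelWeightTable) -> pd.Series:
    """Weighted per-unit mean of one raster, renormalising over non-missing.

    Returns a Series indexed by unit id; NaN when every surviving pixel of
    the unit is missing on that date.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != weights.grid_shape:
        raise ValueError(
            f"raster shape {values.shape} does not match weight grid "
            f"{weights.grid_shape}"
        )
    out = {}
    for uid, grp in weights.table.groupby("unit_id", sort=False):
        v = values[grp["row"].to_numpy(), grp["col"].to_numpy()]
        w = grp["weight"].to_numpy()
        ok = ~np.isnan(v)
        wsum = w[ok].sum()
        out[uid] = float(np.dot(w[ok], v[ok]) / wsum) if wsum > 0 else float("nan")
    for uid in weights.empty_units:
        out[uid] = float("nan")
    return pd.Series(out, name="value")
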