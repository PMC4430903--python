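"""Tile-grid geometry, coordinate transforms, deduplication and picklists.

A slide is scanned as a ``grid_rows x grid_cols`` grid of square camera tiles.
Adjacent fields of view overlap by ``overlap_um`` on all sides so that a cell on
a tile border is imaged whole in at least one tile; the price is that such a
cell is detected more than once and must be deduplicated in slide coordinates.

Conventions: pixel indices are 0-based with ``x = column`` and ``y = row``;
slide coordinates are in micrometres with the origin at the top-left corner of
tile (0, 0); intervals are half-open.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.spatial import cKDTree

from .errors import ConfigurationError

TileIndex = Tuple[int, int]


class SlideLayout(BaseModel):
    """Geometry of the tile grid; defines the tile->slide transform."""

    grid_rows: int = Field(4, ge=1)
    grid_cols: int = Field(4, ge=1)
    tile_px: int = Field(512, ge=32)
    pixel_pitch: float = Field(0.65, gt=0, description="micrometres per pixel")
    overlap_um: float = Field(50.0, ge=0)

    @model_validator(mode="after")
    def _check_stride(self) -> "SlideLayout":
        if self.overlap_um >= self.tile_px * self.pixel_pitch:
            raise ConfigurationError(
                f"overlap ({self.overlap_um} um) must be smaller than the tile "
                f"extent ({self.tile_px * self.pixel_pitch} um)"
            )
        return self

    @property
    def tile_extent_um(self) -> float:
        return self.tile_px * self.pixel_pitch

    @property
    def stride_um(self) -> float:
        """Distance between the origins of adjacent tiles."""
        return self.tile_extent_um - self.overlap_um

    @property
    def slide_extent_um(self) -> Tuple[float, float]:
        """(width, height) of the imaged area in micrometres."""
        w = (self.grid_cols - 1) * self.stride_um + self.tile_extent_um
        h = (self.grid_rows - 1) * self.stride_um + self.tile_extent_um
        return (w, h)

    def tile_origin_um(self, row: int, col: int) -> Tuple[float, float]:
        return (col * self.stride_um, row * self.stride_um)

    def tile_indices(self):
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                yield (r, c)


def tile_to_slide(
    tile_index: TileIndex, px_coord: Tuple[float, float], layout: SlideLayout
) -> Tuple[float, float]:
    """Map a (x, y) pixel coordinate within a tile to slide micrometres."""
    row, col = tile_index
    ox, oy = layout.tile_origin_um(row, col)
    x_px, y_px = px_coord
    return (ox + x_px * layout.pixel_pitch, oy + y_px * layout.pixel_pitch)


def slide_to_tile(
    x_um: float, y_um: float, layout: SlideLayout
) -> Tuple[TileIndex, Tuple[float, float]]:
    """Inverse of :func:`tile_to_slide`.

    A point in an overlap strip belongs to several tiles; the tile whose field
    of view holds the point farthest from its borders is returned (the least
    truncated view), with ties broken toward the smaller (row, col).
    """
    best = None
    for row, col in _candidate_tiles(x_um, y_um, layout):
        ox, oy = layout.tile_origin_um(row, col)
        px = (x_um - ox) / layout.pixel_pitch
        py = (y_um - oy) / layout.pixel_pitch
        if not (0 <= px < layout.tile_px and 0 <= py < layout.tile_px):
            continue
        margin = min(px, py, layout.tile_px - 1 - px, layout.tile_px - 1 - py)
        key = (-margin, row, col)
        if best is None or key < best[0]:
            best = (key, (row, col), (px, py))
    if best is None:
        raise ConfigurationError(f"point ({x_um}, {y_um}) um lies outside the slide")
    return best[1], best[2]


def _candidate_tiles(x_um: float, y_um: float, layout: SlideLayout):
    s = layout.stride_um
    ext = layout.tile_extent_um
    c_lo = max(0, int(np.ceil((x_um - ext) / s)))
    c_hi = min(layout.grid_cols - 1, int(np.floor(x_um / s)))
    r_lo = max(0, int(np.ceil((y_um - ext) / s)))
    r_hi = min(layout.grid_rows - 1, int(np.floor(y_um / s)))
    for r in range(r_lo, r_hi + 1):
        for c in range(c_lo, c_hi + 1):
            yield (r, c)


def border_distance_um(row: pd.Series | np.ndarray, col, cx_px, cy_px, layout: SlideLayout) -> np.ndarray:
    """Distance (um) from a centroid to the nearest border of its own tile."""
    cx = np.asarray(cx_px, dtype=float)
    cy = np.asarray(cy_px, dtype=float)
    m = np.minimum.reduce([cx, cy, layout.tile_px - 1 - cx, layout.tile_px - 1 - cy])
    return m * layout.pixel_pitch


def dedup(detections: pd.DataFrame, layout: SlideLayout, radius_um: float = 15.0) -> pd.DataFrame:
    """Merge duplicate detections of the same physical cell across tiles.

    Detections within ``radius_um`` of each other (single linkage: connected
    components of the proximity graph) are grouped; the representative of each
    group is the member whose centroid lies farthest from its own tile's
    borders, i.e. the least truncated view. Group size is recorded in the
    ``n_merged`` column. Idempotent: representatives of distinct groups are by
    construction more than ``radius_um`` apart.
    """
    df = detections.reset_index(drop=True)
    if df.empty:
        out = df.copy()
        out["n_merged"] = pd.Series(dtype=int)
        return out
    pts = df[["slide_x_um", "slide_y_um"]].to_numpy(float)
    parent = np.arange(len(df))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in cKDTree(pts).query_pairs(radius_um):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(i) for i in range(len(df))])
    margin = border_distance_um(
        df["tile_row"], df["tile_col"], df["centroid_px_x"], df["centroid_px_y"], layout
    )
    reps = []
    sizes = []
    for root in np.unique(roots):
        members = np.flatnonzero(roots == root)
        # farthest from border wins; deterministic tie-break
        order = sorted(
            members,
            key=lambda i: (
                -margin[i],
                int(df.at[i, "tile_row"]),
                int(df.at[i, "tile_col"]),
                str(df.at[i, "object_id"]),
            ),
        )
        reps.append(order[0])
        sizes.append(len(members))
    out = df.loc[reps].copy()
    out["n_merged"] = sizes
    out = out.sort_values(["slide_y_um", "slide_x_um", "object_id"], kind="mergesort")
    return out.reset_index(drop=True)


def build_picklist(
    detections: pd.DataFrame, layout: SlideLayout, band_um: float = 200.0
) -> pd.DataFrame:
    """Ordered coordinate list of confirmed cells for single-cell retrieval.

    Only CELL-labelled detections are listed. Entries are ordered in a
    serpentine pattern — horizontal bands of height ``band_um`` traversed top to
    bottom, alternating left-to-right and right-to-left — to keep stage travel
    short. The order is a pure function of the coordinates, so it is stable
    under permutation of the input rows.
    """
    cells = detections[detections["label"] == "CELL"].copy()
    if cells.empty:
        return pd.DataFrame(
            columns=["cell_id", "slide_x_um", "slide_y_um", "label", "tile_row", "tile_col"]
        )
    band = np.floor(cells["slide_y_um"].to_numpy(float) / band_um).astype(int)
    x = cells["slide_x_um"].to_numpy(float)
    sweep_x = np.where(band % 2 == 0, x, -x)
    cells["_band"] = band
    cells["_sweep"] = sweep_x
    cells = cells.sort_values(
        ["_band", "_sweep", "slide_y_um", "object_id"], kind="mergesort"
    )
    out = cells[["object_id", "slide_x_um", "slide_y_um", "label", "tile_row", "tile_col"]]
    out = out.rename(columns={"object_id": "cell_id"})
    return out.reset_index(drop=True)
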