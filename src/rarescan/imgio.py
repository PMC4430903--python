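"""Readers and writers for tiles, detection tables and glyph crops.

On-disk layout of a tileset directory::

    layout.json              tile grid geometry + ordered channel names
    tile_r000_c000.tif       one multi-page 16-bit TIFF per tile,
    tile_r000_c001.tif       one page per channel in manifest order
    ...

Detection tables are UTF-8 CSV with a fixed header and '.' decimals, one file
per slide. Glyph crops are written as one 16-bit TIFF per channel plus an
optional contrast-stretched 8-bit RGB composite for human review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .slidegeom import SlideLayout

#: canonical channel order used throughout the package
CHANNELS: Tuple[str, ...] = ("nuclear", "ck", "cd45", "marker")

GLYPH_SIZE = 200  # edge length in pixels of the review box around a candidate

VALID_LABELS = ("CELL", "INDETERMINATE", "NOT_A_CELL")

#: fixed detection-table header
DETECTION_COLUMNS: Tuple[str, ...] = (
    "object_id",
    "tile_row",
    "tile_col",
    "centroid_px_x",
    "centroid_px_y",
    "slide_x_um",
    "slide_y_um",
    "area_px",
    "area_um2",
    "equiv_diam_um",
    "mean_nuclear",
    "max_nuclear",
    "mean_ck",
    "max_ck",
    "mean_cd45",
    "max_cd45",
    "mean_marker",
    "max_marker",
    "nuclear_overlap_fraction",
    "cd45_correlation",
    "nc_ratio",
    "nuclear_components",
    "nuc_pos",
    "ck_pos",
    "cd45_pos",
    "marker_pos",
    "candidate",
    "label",
    "rejected_by",
)


@dataclass
class TileImage:
    """One field of view: co-registered per-channel intensity planes.

    ``planes`` maps channel name to a 2-D raster; all planes share one shape.
    ``row``/``col`` index the tile in the slide grid (0-based).
    """

    row: int
    col: int
    planes: Dict[str, np.ndarray]
    pixel_pitch: float

    def __post_init__(self) -> None:
        shapes = {ch: p.shape for ch, p in self.planes.items()}
        if len(set(shapes.values())) > 1:
            raise FormatError(f"tile planes differ in shape: {shapes}")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.planes.values())).shape

    @property
    def channels(self) -> Tuple[str, ...]:
        return tuple(self.planes)

    def copy(self) -> "TileImage":
        return TileImage(
            self.row, self.col, {ch: p.copy() for ch, p in self.planes.items()}, self.pixel_pitch
        )


def _tile_filename(row: int, col: int) -> str:
    return f"tile_r{row:03d}_c{col:03d}.tif"


def write_tileset(
    path: str | Path,
    tiles: Sequence[TileImage],
    layout: SlideLayout,
    channels: Sequence[str] = CHANNELS,
) -> Path:
    """Write tiles as multi-page TIFFs plus a ``layout.json`` manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    channels = tuple(channels)
    for tile in tiles:
        if tile.channels != channels:
            raise FormatError(
                f"tile ({tile.row}, {tile.col}) channels {tile.channels} do not match "
                f"manifest channels {channels}"
            )
        stack = np.stack([np.asarray(tile.planes[ch]) for ch in channels])
        stack = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(
            path / _tile_filename(tile.row, tile.col), stack, photometric="minisblack"
        )
    manifest = {
        "layout": layout.model_dump(),
        "channels": list(channels),
        "tiles": [[t.row, t.col] for t in tiles],
    }
    (path / "layout.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_tileset(path: str | Path) -> Tuple[List[TileImage], SlideLayout, Tuple[str, ...]]:
    """Read a tileset directory written by :func:`write_tileset`."""
    path = Path(path)
    manifest_path = path / "layout.json"
    if not manifest_path.exists():
        raise FormatError(f"missing tileset manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    layout = SlideLayout(**manifest["layout"])
    channels = tuple(manifest["channels"])
    tiles: List[TileImage] = []
    for row, col in manifest["tiles"]:
        fn = path / _tile_filename(row, col)
        if not fn.exists():
            raise FormatError(f"missing tile file for tile ({row}, {col}): {fn}")
        stack = tifffile.imread(fn)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != len(channels):
            raise FormatError(
                f"tile ({row}, {col}) has {stack.shape[0]} channel pages, "
                f"manifest declares {len(channels)}"
            )
        planes = {ch: stack[i] for i, ch in enumerate(channels)}
        tiles.append(TileImage(row, col, planes, layout.pixel_pitch))
    return tiles, layout, channels


def write_detections(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a detection table as CSV with >= 6 significant digits."""
    path = Path(path)
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"detection table is missing columns: {missing}")
    extra = [c for c in table.columns if c not in DETECTION_COLUMNS]
    ordered = table[list(DETECTION_COLUMNS) + extra]
    ordered.to_csv(path, index=False, float_format="%.9g")
    return path


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detection CSV, validating the header and the label column."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"detection table {path} is missing columns: {missing}")
    if len(table):
        bad = set(table["label"].astype(str)) - set(VALID_LABELS)
        if bad:
            raise FormatError(f"unknown label value(s) in {path}: {sorted(bad)}")
    return table


@dataclass
class Glyph:
    """A fixed-size per-channel crop of a candidate object for review."""

    object_id: str
    images: Dict[str, np.ndarray]  # each GLYPH_SIZE x GLYPH_SIZE
    center_px: Tuple[int, int]  # (x, y) in the source tile
    pad_offset: Tuple[int, int] = (0, 0)  # (rows, cols) of zero padding at top-left

    def __post_init__(self) -> None:
        for ch, img in self.images.items():
            if img.shape != (GLYPH_SIZE, GLYPH_SIZE):
                raise FormatError(
                    f"glyph channel {ch} has shape {img.shape}, expected "
                    f"({GLYPH_SIZE}, {GLYPH_SIZE})"
                )


def write_glyph(glyph: Glyph, out_dir: str | Path, composite: bool = True) -> List[Path]:
    """Write one 16-bit TIFF per channel, plus an optional RGB composite.

    Filenames encode the object id: ``<object_id>_<channel>.tif``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    for ch, img in glyph.images.items():
        p = out_dir / f"{glyph.object_id}_{ch}.tif"
        tifffile.imwrite(p, np.clip(np.rint(img), 0, 65535).astype(np.uint16))
        paths.append(p)
    if composite:
        rgb = _composite_rgb(glyph.images)
        p = out_dir / f"{glyph.object_id}_rgb.tif"
        tifffile.imwrite(p, rgb)
        paths.append(p)
    return paths


def _stretch(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.clip(255.0 * (img - lo) / (hi - lo), 0, 255).astype(np.uint8)


def _composite_rgb(images: Dict[str, np.ndarray]) -> np.ndarray:
    """Review composite: marker/CD45 -> red, CK -> green, nuclear -> blue."""
    shape = next(iter(images.values())).shape
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    red = images.get("marker", images.get("cd45"))
    if red is not None:
        rgb[..., 0] = _stretch(red)
    if "ck" in images:
        rgb[..., 1] = _stretch(images["ck"])
    if "nuclear" in images:
        rgb[..., 2] = _stretch(images["nuclear"])
    return rgb
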