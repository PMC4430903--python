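"""Synthetic tiled 4-channel slide simulator with known ground truth.

The simulator emulates a buffy-coat preparation spread on a slide and scanned
as an overlapping grid of 4-channel fluorescence fields of view (nuclear dye,
cytokeratin, CD45, and an auxiliary epithelial marker such as EpCAM/EGFR).
Four cell populations are modelled:

* ``MCTC``    — model circulating tumor cell: nucleated, cytokeratin-positive,
  CD45-negative, with a membrane rim of auxiliary marker.
* ``WBC``     — white blood cell: nucleated, CD45-positive, CK-negative.
* ``SQUAMOUS``— venipuncture skin contaminant: very large, dim CK-positive
  area with a normal-size nucleus (low nuclear:cytoplasm area ratio),
  CD45-negative.
* ``DEBRIS``  — small anucleate CK-positive fragment.

Cells are rendered as truncated Gaussian intensity disks (sigma = radius / 2,
truncated at 2.5 sigma), which are smooth, closed-form integrable and cheap.
Noise is additive Gaussian clipped at zero on top of a linear background
gradient; intensities live on the unsigned 16-bit scale [0, 65535].

Geometry is expressed in slide micrometres and rendered independently into
every tile whose field of view reaches the cell, so a cell in an overlap strip
appears in all adjacent tiles (with independent per-tile noise, as separate
camera exposures would have).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import ndimage as ndi

from .errors import ConfigurationError
from .imgio import CHANNELS, TileImage
from .slidegeom import SlideLayout

POPULATIONS = ("wbc", "mctc", "squamous", "debris")

#: default per-population per-channel amplitude ranges (16-bit counts)
DEFAULT_AMPLITUDES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "wbc": {"nuclear": (6000.0, 12000.0), "cd45": (5000.0, 10000.0)},
    "mctc": {
        "nuclear": (6000.0, 12000.0),
        "ck": (6000.0, 10000.0),
        "marker": (3000.0, 6000.0),
    },
    "squamous": {"nuclear": (6000.0, 12000.0), "ck": (1500.0, 2500.0)},
    "debris": {"ck": (1000.0, 3000.0)},
}

#: default (nuclear_radius_um, cytoplasm_radius_um) per population.
#: WBC ~9 um diameter; mCTC ~15 um with a large nucleus; squamous contaminants
#: have a cytoplasm 3x the mCTC default with a normal nucleus, giving a
#: nuclear:cytoplasm area ratio < 0.1; debris has no nucleus.
DEFAULT_GEOMETRY: Dict[str, Tuple[float, float]] = {
    "wbc": (3.5, 4.5),
    "mctc": (5.0, 7.5),
    "squamous": (5.0, 22.5),
    "debris": (0.0, 1.5),
}

TRUNC_SIGMA = 2.5  # radial profiles are cut at this many sigma


class ClusterSpec(BaseModel):
    """Optional mCTC clusters: cells placed tightly around shared centers."""

    n_clusters: int = Field(0, ge=0)
    cells_per_cluster: int = Field(0, ge=0)
    spread_um: float = Field(6.0, gt=0)


class SimConfig(BaseModel):
    """Everything needed to generate one synthetic slide deterministically."""

    grid_rows: int = Field(4, ge=1)
    grid_cols: int = Field(4, ge=1)
    tile_px: int = Field(512, ge=32)
    pixel_pitch: float = Field(0.65, gt=0, description="micrometres per pixel")
    overlap_um: float = Field(50.0, ge=0)
    channels: Tuple[str, ...] = CHANNELS
    background_level: float = Field(500.0, ge=0)
    background_gradient: float = Field(
        50.0, description="intensity units per mm along slide x"
    )
    noise_sd: float = Field(50.0, ge=0)
    counts: Dict[str, int] = Field(
        default={"wbc": 2000, "mctc": 5, "squamous": 0, "debris": 0}
    )
    amplitudes: Dict[str, Dict[str, Tuple[float, float]]] = Field(
        default=DEFAULT_AMPLITUDES
    )
    geometry: Dict[str, Tuple[float, float]] = Field(default=DEFAULT_GEOMETRY)
    chromatic_shift: Dict[str, Tuple[float, float]] = Field(
        default={}, description="per non-reference channel (dx, dy) in pixels"
    )
    cluster_spec: Optional[ClusterSpec] = None
    min_separation_um: float = Field(30.0, ge=0)
    edge_margin_um: float = Field(30.0, ge=0)
    seed: int = 0

    @field_validator("counts")
    @classmethod
    def _counts_nonneg(cls, v: Dict[str, int]) -> Dict[str, int]:
        for pop, n in v.items():
            if pop not in POPULATIONS:
                raise ValueError(f"unknown population {pop!r}")
            if n < 0:
                raise ValueError(f"count for {pop!r} must be >= 0, got {n}")
        return v

    @field_validator("amplitudes")
    @classmethod
    def _amp_ranges(cls, v):
        for pop, chans in v.items():
            for ch, (lo, hi) in chans.items():
                if lo < 0 or hi < lo:
                    raise ValueError(
                        f"amplitude range for {pop}/{ch} must satisfy 0 <= lo <= hi"
                    )
        return v

    @model_validator(mode="after")
    def _check_geometry(self) -> "SimConfig":
        if self.overlap_um >= self.tile_px * self.pixel_pitch:
            raise ConfigurationError(
                f"overlap ({self.overlap_um} um) must be smaller than the tile "
                f"extent ({self.tile_px * self.pixel_pitch} um)"
            )
        return self

    def layout(self) -> SlideLayout:
        return SlideLayout(
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            tile_px=self.tile_px,
            pixel_pitch=self.pixel_pitch,
            overlap_um=self.overlap_um,
        )


@dataclass
class TruthRecord:
    """Ground truth for one synthetic cell."""

    cell_id: str
    population: str  # WBC | MCTC | SQUAMOUS | DEBRIS
    x_um: float
    y_um: float
    nuclear_radius_um: float
    cytoplasm_radius_um: float
    amplitudes: Dict[str, float]
    cluster_id: Optional[str] = None
    aspect: float = 1.0  # minor/major axis ratio (debris irregularity)
    theta: float = 0.0  # orientation of the major axis, radians


@dataclass
class TruthManifest:
    """All ground-truth records for a slide plus the config that made them."""

    records: List[TruthRecord]
    config: SimConfig
    seed: int

    def counts(self) -> Dict[str, int]:
        out = {p.upper(): 0 for p in POPULATIONS}
        for rec in self.records:
            out[rec.population] = out.get(rec.population, 0) + 1
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "config": self.config.model_dump(),
            "records": [asdict(r) for r in self.records],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        records = [TruthRecord(**r) for r in payload["records"]]
        return cls(records=records, config=SimConfig(**payload["config"]), seed=payload["seed"])

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "cell_id": r.cell_id,
                "population": r.population,
                "x_um": r.x_um,
                "y_um": r.y_um,
                "nuclear_radius_um": r.nuclear_radius_um,
                "cytoplasm_radius_um": r.cytoplasm_radius_um,
                "cluster_id": r.cluster_id or "",
            }
            for ch in self.config.channels:
                row[f"amp_{ch}"] = r.amplitudes.get(ch, 0.0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
        return Path(path)


# ---------------------------------------------------------------------------
# truth sampling
# ---------------------------------------------------------------------------


def sample_truth(cfg: SimConfig) -> TruthManifest:
    """Draw cell positions and amplitudes for one slide.

    WBCs are placed uniformly over the usable slide extent with overlaps
    allowed (crowding is part of the model). Rare cells (mCTC, squamous,
    debris) are rejection-resampled until they keep ``min_separation_um`` from
    every previously placed cell, so each is imaged on a locally clean patch —
    except members of a declared cluster, which pack around their center.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    w, h = layout.slide_extent_um
    m = cfg.edge_margin_um
    if 2 * m >= min(w, h):
        raise ConfigurationError("edge margin leaves no usable slide area")

    placed: List[Tuple[float, float]] = []
    records: List[TruthRecord] = []

    def uniform_xy() -> Tuple[float, float]:
        return (rng.uniform(m, w - m), rng.uniform(m, h - m))

    def separated_xy(clearance: float, max_tries: int = 20000) -> Tuple[float, float]:
        arr = np.asarray(placed) if placed else None
        for _ in range(max_tries):
            x, y = uniform_xy()
            if arr is None or len(arr) == 0:
                return (x, y)
            d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
            if d2.min() >= clearance**2:
                return (x, y)
            arr = np.asarray(placed)
        raise ConfigurationError(
            f"could not place a cell with {clearance} um clearance after "
            f"{max_tries} attempts; slide too crowded"
        )

    def draw_amplitudes(pop: str) -> Dict[str, float]:
        amps = {}
        for ch in cfg.channels:
            lo, hi = cfg.amplitudes.get(pop, {}).get(ch, (0.0, 0.0))
            amps[ch] = float(rng.uniform(lo, hi)) if hi > 0 else 0.0
        return amps

    def make_record(pop: str, idx: int, x: float, y: float, cluster_id=None) -> TruthRecord:
        nuc_r, cyt_r = cfg.geometry[pop]
        aspect, theta = 1.0, 0.0
        if pop == "debris":
            aspect = float(rng.uniform(0.3, 0.7))
            theta = float(rng.uniform(0, math.pi))
        return TruthRecord(
            cell_id=f"{pop.upper()}-{idx:05d}",
            population=pop.upper(),
            x_um=x,
            y_um=y,
            nuclear_radius_um=nuc_r,
            cytoplasm_radius_um=cyt_r,
            amplitudes=draw_amplitudes(pop),
            cluster_id=cluster_id,
            aspect=aspect,
            theta=theta,
        )

    # abundant population first so rare cells can clear it
    for i in range(cfg.counts.get("wbc", 0)):
        x, y = uniform_xy()
        placed.append((x, y))
        records.append(make_record("wbc", i, x, y))

    for pop in ("mctc", "squamous", "debris"):
        for i in range(cfg.counts.get(pop, 0)):
            x, y = separated_xy(cfg.min_separation_um)
            placed.append((x, y))
            records.append(make_record(pop, i, x, y))

    if cfg.cluster_spec is not None and cfg.cluster_spec.n_clusters > 0:
        spec = cfg.cluster_spec
        base = cfg.counts.get("mctc", 0)
        for k in range(spec.n_clusters):
            clearance = cfg.min_separation_um + 3 * spec.spread_um
            cx, cy = separated_xy(clearance)
            for j in range(spec.cells_per_cluster):
                x = float(np.clip(cx + rng.normal(0, spec.spread_um), m, w - m))
                y = float(np.clip(cy + rng.normal(0, spec.spread_um), m, h - m))
                placed.append((x, y))
                records.append(
                    make_record("mctc", base + k * spec.cells_per_cluster + j, x, y, f"cluster-{k:03d}")
                )

    return TruthManifest(records=records, config=cfg, seed=cfg.seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _add_disk(plane: np.ndarray, cx: float, cy: float, sigma_px: float, amp: float) -> None:
    """Add a truncated Gaussian disk peaking at ``amp`` at (cx, cy)."""
    if amp <= 0 or sigma_px <= 0:
        return
    r = TRUNC_SIGMA * sigma_px
    h, w = plane.shape
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    prof = amp * np.exp(-d2 / (2.0 * sigma_px**2))
    prof[d2 > r**2] = 0.0
    plane[y0:y1, x0:x1] += prof


def _add_ring(
    plane: np.ndarray, cx: float, cy: float, r0_px: float, sigma_px: float, amp: float
) -> None:
    """Add an annular Gaussian profile peaking at ``amp`` on the ring radius."""
    if amp <= 0 or sigma_px <= 0:
        return
    r = r0_px + TRUNC_SIGMA * sigma_px
    h, w = plane.shape
    x0, x1 = max(0, int(math.floor(cx - r))), min(w, int(math.ceil(cx + r)) + 1)
    y0, y1 = max(0, int(math.floor(cy - r))), min(h, int(math.ceil(cy + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
    prof = amp * np.exp(-((d - r0_px) ** 2) / (2.0 * sigma_px**2))
    prof[np.abs(d - r0_px) > TRUNC_SIGMA * sigma_px] = 0.0
    plane[y0:y1, x0:x1] += prof


def _add_aniso(
    plane: np.ndarray,
    cx: float,
    cy: float,
    sigma_px: float,
    aspect: float,
    theta: float,
    amp: float,
) -> None:
    """Anisotropic Gaussian fragment (debris)."""
    if amp <= 0 or sigma_px <= 0:
        return
    r = TRUNC_SIGMA * sigma_px
    h, w = plane.shape
    x0, x1 = max(0, int(math.floor(cx - r))), min(w, int(math.ceil(cx + r)) + 1)
    y0, y1 = max(0, int(math.floor(cy - r))), min(h, int(math.ceil(cy + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    su, sv = sigma_px, max(aspect * sigma_px, 1e-6)
    q2 = (u / su) ** 2 + (v / sv) ** 2
    prof = amp * np.exp(-q2 / 2.0)
    prof[q2 > TRUNC_SIGMA**2] = 0.0
    plane[y0:y1, x0:x1] += prof


def render_cell(canvas: TileImage, rec: TruthRecord, cfg: SimConfig) -> TileImage:
    """Render one truth record into a tile canvas (in place; noise-free).

    Population phenotypes: MCTC = nuclear disk + cytoplasmic CK + marker rim;
    WBC = nuclear disk + CD45 disk; SQUAMOUS = large dim CK disk with a normal
    nucleus; DEBRIS = small anisotropic CK fragment, no nucleus. Records whose
    profile does not reach the tile are a no-op.
    """
    layout = cfg.layout()
    ox, oy = layout.tile_origin_um(canvas.row, canvas.col)
    pitch = cfg.pixel_pitch
    cx = (rec.x_um - ox) / pitch
    cy = (rec.y_um - oy) / pitch
    nuc_sigma = rec.nuclear_radius_um / 2.0 / pitch
    cyt_sigma = rec.cytoplasm_radius_um / 2.0 / pitch
    amps = rec.amplitudes
    pop = rec.population.upper()

    if pop in ("WBC", "MCTC", "SQUAMOUS") and "nuclear" in canvas.planes:
        _add_disk(canvas.planes["nuclear"], cx, cy, nuc_sigma, amps.get("nuclear", 0.0))
    if pop == "WBC" and "cd45" in canvas.planes:
        _add_disk(canvas.planes["cd45"], cx, cy, cyt_sigma, amps.get("cd45", 0.0))
    if pop in ("MCTC", "SQUAMOUS") and "ck" in canvas.planes:
        _add_disk(canvas.planes["ck"], cx, cy, cyt_sigma, amps.get("ck", 0.0))
    if pop == "MCTC" and "marker" in canvas.planes:
        r0_px = 0.8 * rec.cytoplasm_radius_um / pitch
        _add_ring(
            canvas.planes["marker"], cx, cy, r0_px, rec.cytoplasm_radius_um / 4.0 / pitch,
            amps.get("marker", 0.0),
        )
    if pop == "DEBRIS" and "ck" in canvas.planes:
        _add_aniso(
            canvas.planes["ck"], cx, cy, cyt_sigma, rec.aspect, rec.theta, amps.get("ck", 0.0)
        )
    return canvas


def apply_chromatic_shift(
    tile: TileImage, shifts: Dict[str, Tuple[float, float]]
) -> TileImage:
    """Translate named channels by (dx, dy) pixels (bilinear for fractional).

    The reference channel (any channel absent from ``shifts`` or with a zero
    shift) is left untouched, bit for bit. Shifts at least as large as the
    tile raise a :class:`ConfigurationError`.
    """
    h, w = tile.shape
    out_planes: Dict[str, np.ndarray] = {}
    for ch, plane in tile.planes.items():
        dx, dy = shifts.get(ch, (0.0, 0.0))
        if abs(dx) >= w or abs(dy) >= h:
            raise ConfigurationError(
                f"chromatic shift ({dx}, {dy}) px exceeds tile shape {(h, w)}"
            )
        if dx == 0 and dy == 0:
            out_planes[ch] = plane.copy()
        else:
            shifted = ndi.shift(
                np.asarray(plane, dtype=float), (dy, dx), order=1, mode="nearest"
            )
            out_planes[ch] = shifted
    return TileImage(tile.row, tile.col, out_planes, tile.pixel_pitch)


def _background(cfg: SimConfig, row: int, col: int) -> np.ndarray:
    layout = cfg.layout()
    ox, _ = layout.tile_origin_um(row, col)
    x_um = ox + np.arange(cfg.tile_px) * cfg.pixel_pitch
    level = cfg.background_level + cfg.background_gradient * (x_um / 1000.0)
    return np.broadcast_to(level, (cfg.tile_px, cfg.tile_px)).copy()


def render_slide(truth: TruthManifest, cfg: SimConfig) -> List[TileImage]:
    """Render a truth manifest into the tile grid defined by ``cfg``.

    Deterministic for fixed truth + config: per-tile noise streams are seeded
    from (cfg.seed, tile row, tile col).
    """
    tiles: List[TileImage] = []
    for row, col in cfg.layout().tile_indices():
        planes = {ch: _background(cfg, row, col) for ch in cfg.channels}
        tile = TileImage(row, col, planes, cfg.pixel_pitch)
        for rec in truth.records:
            render_cell(tile, rec, cfg)
        if any(tuple(s) != (0.0, 0.0) for s in cfg.chromatic_shift.values()):
            tile = apply_chromatic_shift(tile, cfg.chromatic_shift)
        if cfg.noise_sd > 0:
            noise_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 7919, row, col])
            for ch in cfg.channels:
                tile.planes[ch] += noise_rng.normal(0.0, cfg.noise_sd, tile.shape)
        for ch in cfg.channels:
            tile.planes[ch] = (
                np.clip(np.rint(tile.planes[ch]), 0, 65535).astype(np.uint16)
            )
        tiles.append(tile)
    return tiles


def generate_slide(cfg: SimConfig) -> Tuple[List[TileImage], TruthManifest]:
    """Sample ground truth and render the full tiled slide."""
    truth = sample_truth(cfg)
    tiles = render_slide(truth, cfg)
    return tiles, truth


def simulate_calibration_tile(
    cfg: SimConfig, n_beads: int = 25, amplitude: float = 20000.0, seed: Optional[int] = None
) -> TileImage:
    """A bead field visible in every channel, for channel registration.

    The configured chromatic shift is applied to the bead image, so the true
    per-channel displacements are ``cfg.chromatic_shift``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.tile_px
    margin = 20
    xs = rng.uniform(margin, n - margin, n_beads)
    ys = rng.uniform(margin, n - margin, n_beads)
    base = np.full((n, n), cfg.background_level, dtype=float)
    for x, y in zip(xs, ys):
        _add_disk(base, x, y, 2.0, amplitude)
    tile = TileImage(0, 0, {ch: base.copy() for ch in cfg.channels}, cfg.pixel_pitch)
    tile = apply_chromatic_shift(tile, cfg.chromatic_shift)
    if cfg.noise_sd > 0:
        for ch in cfg.channels:
            tile.planes[ch] += rng.normal(0.0, cfg.noise_sd, tile.shape)
    for ch in cfg.channels:
        tile.planes[ch] = np.clip(np.rint(tile.planes[ch]), 0, 65535).astype(np.uint16)
    return tile
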