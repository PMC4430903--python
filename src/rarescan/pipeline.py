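"""Whole-slide scan pipeline: threshold -> segment -> measure -> classify -> dedup."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import ClassLabel, RuleConfig, classify
from .detectcore import (
    DEFAULT_K,
    DEFAULT_MAX_AREA_UM2,
    DEFAULT_MIN_AREA_UM2,
    estimate_threshold,
    extract_features,
    segment_primary,
)
from .imgio import DETECTION_COLUMNS, TileImage
from .simslide import apply_chromatic_shift
from .slidegeom import SlideLayout, build_picklist, dedup, tile_to_slide

DEFAULT_DEDUP_RADIUS_UM = 15.0


@dataclass
class ScanResult:
    """Everything the scan of one slide produces."""

    detections: pd.DataFrame  # every per-tile detection
    unique: pd.DataFrame  # after cross-tile deduplication
    picklist: pd.DataFrame  # CELL coordinates in retrieval order
    summary: Dict[str, object]


def scan_tile(
    tile: TileImage,
    layout: SlideLayout,
    rules: RuleConfig,
    k: float = DEFAULT_K,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
) -> List[Dict[str, object]]:
    """Detect, measure and classify objects on one tile."""
    models = {ch: estimate_threshold(tile.planes[ch], k, ch) for ch in tile.channels}
    masks = segment_primary(
        tile.planes["ck"],
        models["ck"],
        layout.pixel_pitch,
        min_area_um2=min_area_um2,
        max_area_um2=max_area_um2,
        tile_row=tile.row,
        tile_col=tile.col,
    )
    rows: List[Dict[str, object]] = []
    for idx, mask in enumerate(masks):
        feats = extract_features(tile, mask, models)
        label, candidate, rejected_by = classify(feats, models, rules)
        cx, cy = mask.centroid_px
        sx, sy = tile_to_slide((tile.row, tile.col), (cx, cy), layout)
        rows.append(
            {
                "object_id": f"t{tile.row:02d}c{tile.col:02d}-{idx:03d}",
                "tile_row": tile.row,
                "tile_col": tile.col,
                "centroid_px_x": cx,
                "centroid_px_y": cy,
                "slide_x_um": sx,
                "slide_y_um": sy,
                "area_px": mask.area_px,
                "area_um2": mask.area_um2,
                "equiv_diam_um": feats.equiv_diam_um,
                "mean_nuclear": feats.means["nuclear"],
                "max_nuclear": feats.maxes["nuclear"],
                "mean_ck": feats.means["ck"],
                "max_ck": feats.maxes["ck"],
                "mean_cd45": feats.means["cd45"],
                "max_cd45": feats.maxes["cd45"],
                "mean_marker": feats.means["marker"],
                "max_marker": feats.maxes["marker"],
                "nuclear_overlap_fraction": feats.nuclear_overlap_fraction,
                "cd45_correlation": feats.cd45_correlation,
                "nc_ratio": feats.nc_ratio,
                "nuclear_components": feats.nuclear_components,
                "nuc_pos": feats.nuclear_overlap_fraction >= rules.min_nuclear_overlap,
                "ck_pos": True,  # segmented objects are supra-threshold by construction
                "cd45_pos": feats.means["cd45"]
                >= rules.threshold_overrides.get("cd45", models["cd45"].threshold),
                "marker_pos": feats.means["marker"]
                >= rules.threshold_overrides.get("marker", models["marker"].threshold),
                "candidate": candidate,
                "label": label.value,
                "rejected_by": rejected_by.value,
            }
        )
    return rows


def scan_tiles(
    tiles: Sequence[TileImage],
    layout: SlideLayout,
    rules: Optional[RuleConfig] = None,
    k: float = DEFAULT_K,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    dedup_radius_um: float = DEFAULT_DEDUP_RADIUS_UM,
    shifts: Optional[Dict[str, Tuple[float, float]]] = None,
) -> ScanResult:
    """Scan a full tileset.

    ``shifts`` (per-channel chromatic displacements, e.g. estimated by
    :func:`rarescan.detectcore.register_channels`) are compensated by applying
    the negated shift before detection. Detections in overlap strips are
    deduplicated in slide coordinates.
    """
    rules = rules or RuleConfig()
    rows: List[Dict[str, object]] = []
    for tile in tiles:
        if shifts:
            neg = {ch: (-dx, -dy) for ch, (dx, dy) in shifts.items()}
            tile = apply_chromatic_shift(tile, neg)
        rows.extend(
            scan_tile(
                tile, layout, rules, k=k, min_area_um2=min_area_um2, max_area_um2=max_area_um2
            )
        )
    detections = pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))
    unique = dedup(detections, layout, dedup_radius_um)
    picklist = build_picklist(unique, layout)
    label_counts = (
        unique["label"].value_counts().to_dict() if len(unique) else {}
    )
    summary: Dict[str, object] = {
        "n_tiles": len(tiles),
        "n_detections": int(len(detections)),
        "n_unique": int(len(unique)),
        "n_candidates": int(unique["candidate"].sum()) if len(unique) else 0,
        "n_cell": int(label_counts.get(ClassLabel.CELL.value, 0)),
        "n_indeterminate": int(label_counts.get(ClassLabel.INDETERMINATE.value, 0)),
        "n_not_a_cell": int(label_counts.get(ClassLabel.NOT_A_CELL.value, 0)),
        "k": k,
        "dedup_radius_um": dedup_radius_um,
        "rules": rules.model_dump(),
    }
    return ScanResult(detections=detections, unique=unique, picklist=picklist, summary=summary)
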