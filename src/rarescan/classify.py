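"""Rule-based object classification: Cell / Indeterminate / Not-a-Cell.

The classifier operationalizes the review criteria for cells of epithelial
origin: a **Cell** is nucleated, cytokeratin-positive and CD45-negative; an
object whose CK signal is highly correlated with CD45 is rejected outright as
a stained leukocyte or artifact; mixed-marker objects are **Indeterminate**;
everything else is **Not a Cell**. A separate morphology gate (maximum area
and minimum nuclear:cytoplasm area ratio) demotes squamous skin contaminants
that meet the marker criteria — these still count as automated *candidates*
(they would be presented for review) but not as final Cells.

The auxiliary marker channel (EpCAM/EGFR/Ki-67) is interpretive only: it can
rescue an anucleate CK+ object into Indeterminate but never vetoes a Cell.
All cutoffs live in :class:`RuleConfig`; ties at a threshold resolve to
positive (``>=``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field

from .detectcore import ObjectFeatures, ThresholdModel
from .imgio import GLYPH_SIZE, Glyph, TileImage


class ClassLabel(str, enum.Enum):
    CELL = "CELL"
    INDETERMINATE = "INDETERMINATE"
    NOT_A_CELL = "NOT_A_CELL"


class RejectReason(str, enum.Enum):
    CD45_CORRELATION = "cd45_correlation"
    CD45_POSITIVE = "cd45_positive"
    NO_NUCLEUS = "no_nucleus"
    MORPHOLOGY = "morphology"
    NONE = "none"


class RuleConfig(BaseModel):
    """Classification cutoffs; all exposed so no rule requires a code change."""

    corr_reject_r: float = Field(0.5, gt=0, le=1, description="CD45 correlation cutoff")
    min_nuclear_overlap: float = Field(0.2, ge=0, le=1)
    max_area_um2_cell: float = Field(700.0, gt=0, description="morphology gate: max area")
    min_nc_ratio: float = Field(0.15, ge=0, le=1, description="morphology gate: min N:C")
    threshold_overrides: Dict[str, float] = Field(
        default={}, description="fixed per-channel positivity thresholds, if any"
    )


def _positivity_threshold(
    channel: str, thresholds: Dict[str, ThresholdModel], rules: RuleConfig
) -> float:
    if channel in rules.threshold_overrides:
        return rules.threshold_overrides[channel]
    return thresholds[channel].threshold


def call_positivity(
    features: ObjectFeatures,
    thresholds: Dict[str, ThresholdModel],
    rules: RuleConfig,
) -> Dict[str, bool]:
    """Per-channel positivity flags for one object.

    CK, CD45 and marker are positive when the mean intensity within the mask
    reaches the channel threshold; nuclear positivity means the object carries
    a nucleus (nuclear overlap fraction at least ``min_nuclear_overlap``).
    """
    return {
        "nuc": features.nuclear_overlap_fraction >= rules.min_nuclear_overlap,
        "ck": features.means["ck"] >= _positivity_threshold("ck", thresholds, rules),
        "cd45": features.means["cd45"] >= _positivity_threshold("cd45", thresholds, rules),
        "marker": features.means["marker"]
        >= _positivity_threshold("marker", thresholds, rules),
    }


def classify(
    features: ObjectFeatures,
    thresholds: Dict[str, ThresholdModel],
    rules: RuleConfig,
) -> Tuple[ClassLabel, bool, RejectReason]:
    """Deterministic decision table -> (label, candidate_flag, rejected_by).

    Evaluated in order:

    1. CD45-correlated and CD45-positive -> NOT_A_CELL (correlation rejection).
    2. CK+ and nucleated and CD45- -> *candidate*; CELL if the morphology gate
       passes (area <= max_area_um2_cell and N:C >= min_nc_ratio), otherwise
       NOT_A_CELL (morphology).
    3. CK+ and CD45+ (below the correlation cutoff) -> INDETERMINATE.
    4. CK+, anucleate, marker+ -> INDETERMINATE.
    5. Otherwise NOT_A_CELL.

    ``candidate_flag`` marks objects that would be presented for human review
    (CK+/nucleated/CD45-) independently of the final label, so contaminants
    demoted by morphology remain countable as candidates.
    """
    flags = call_positivity(features, thresholds, rules)

    if features.cd45_correlation >= rules.corr_reject_r and flags["cd45"]:
        return ClassLabel.NOT_A_CELL, False, RejectReason.CD45_CORRELATION

    if flags["ck"] and flags["nuc"] and not flags["cd45"]:
        passes_morphology = (
            features.area_um2 <= rules.max_area_um2_cell
            and features.nc_ratio >= rules.min_nc_ratio
        )
        if passes_morphology:
            return ClassLabel.CELL, True, RejectReason.NONE
        return ClassLabel.NOT_A_CELL, True, RejectReason.MORPHOLOGY

    if flags["ck"] and flags["cd45"]:
        return ClassLabel.INDETERMINATE, False, RejectReason.NONE

    if flags["ck"] and not flags["nuc"] and flags["marker"]:
        return ClassLabel.INDETERMINATE, False, RejectReason.NONE

    if flags["ck"] and not flags["nuc"]:
        return ClassLabel.NOT_A_CELL, False, RejectReason.NO_NUCLEUS
    if flags["cd45"] and not flags["ck"]:
        return ClassLabel.NOT_A_CELL, False, RejectReason.CD45_POSITIVE
    return ClassLabel.NOT_A_CELL, False, RejectReason.NONE


def make_glyph(
    tile: TileImage, centroid_px: Tuple[float, float], object_id: str
) -> Glyph:
    """Cut the 200 x 200 pixel review box around an object centroid.

    The crop is centered on the rounded centroid; regions falling off the tile
    are zero-padded and the padding offset is recorded, so every glyph is
    exactly 200 x 200 regardless of position.
    """
    half = GLYPH_SIZE // 2
    cx, cy = int(round(centroid_px[0])), int(round(centroid_px[1]))
    h, w = tile.shape
    r0, r1 = cy - half, cy + half
    c0, c1 = cx - half, cx + half
    sr0, sr1 = max(0, r0), min(h, r1)
    sc0, sc1 = max(0, c0), min(w, c1)
    pad_top, pad_left = sr0 - r0, sc0 - c0
    images: Dict[str, np.ndarray] = {}
    for ch, plane in tile.planes.items():
        crop = np.zeros((GLYPH_SIZE, GLYPH_SIZE), dtype=np.asarray(plane).dtype)
        if sr0 < sr1 and sc0 < sc1:
            crop[
                pad_top : pad_top + (sr1 - sr0), pad_left : pad_left + (sc1 - sc0)
            ] = np.asarray(plane)[sr0:sr1, sc0:sc1]
        images[ch] = crop
    return Glyph(
        object_id=object_id, images=images, center_px=(cx, cy), pad_offset=(pad_top, pad_left)
    )
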