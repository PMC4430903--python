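"""Per-tile detection core: registration, thresholding, segmentation, features.

Primary detection runs on the cytokeratin (CK) channel. Signal is separated
from background with a per-tile robust threshold

    threshold = median + k * 1.4826 * MAD

where the median and MAD are taken over the whole tile (robust to the sparse
bright objects that would bias a mean/SD estimate) and 1.4826 scales the MAD
to a normal-equivalent standard deviation. Supra-threshold pixels are grouped
into 8-connected, hole-filled components, gated on area, and measured; each
object's correlation with the CD45 channel (the leukocyte exclusion marker)
and nuclear content are attached for the downstream classifier.

The nuclear channel is never used for primary detection; its threshold is
computed the same way but only drives nuclear-overlap and N:C measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .errors import CalibrationError
from .imgio import TileImage

MAD_TO_SD = 1.4826  # normal-consistency factor for the MAD

DEFAULT_K = 6.0
DEFAULT_MIN_AREA_UM2 = 20.0
DEFAULT_MAX_AREA_UM2 = 2000.0


@dataclass(frozen=True)
class ThresholdModel:
    """Robust per-tile background model for one channel."""

    channel: str
    background_median: float
    background_mad: float
    k: float
    threshold: float
    degenerate: bool = False  # MAD == 0 (e.g. constant plane)


def estimate_threshold(plane: np.ndarray, k: float = DEFAULT_K, channel: str = "") -> ThresholdModel:
    """Adaptive auto-threshold: median + k * 1.4826 * MAD over the whole tile."""
    plane = np.asarray(plane)
    if plane.size == 0:
        raise ValueError("cannot estimate a threshold on an empty plane")
    med = float(np.median(plane))
    mad = float(np.median(np.abs(plane.astype(float) - med)))
    thr = med + k * MAD_TO_SD * mad
    return ThresholdModel(
        channel=channel,
        background_median=med,
        background_mad=mad,
        k=k,
        threshold=thr,
        degenerate=(mad == 0.0),
    )


@dataclass
class ObjectMask:
    """One segmented CK object: pixel support and basic geometry."""

    tile_row: int
    tile_col: int
    bbox: Tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    mask: np.ndarray  # bool array of bbox shape
    area_px: int
    area_um2: float
    centroid_px: Tuple[float, float]  # (x, y), sub-pixel, intensity-weighted
    pixel_pitch: float

    def full_mask(self, shape: Tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def segment_primary(
    ck_plane: np.ndarray,
    model: ThresholdModel,
    pixel_pitch: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    tile_row: int = 0,
    tile_col: int = 0,
) -> List[ObjectMask]:
    """Segment supra-threshold CK signal into candidate objects.

    8-connected components of ``plane > threshold`` are hole-filled, gated on
    area in square micrometres, and returned in deterministic row-major order
    of their bounding-box origin. Centroids are weighted by background-
    subtracted intensity.
    """
    plane = np.asarray(ck_plane, dtype=float)
    binary = plane > model.threshold
    if not binary.any():
        return []
    filled = ndi.binary_fill_holes(binary)
    labels = measure.label(filled, connectivity=2)
    px_area_um2 = pixel_pitch**2
    objects: List[ObjectMask] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area_um2
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        r0, c0, r1, c1 = region.bbox
        sub = plane[r0:r1, c0:c1]
        msk = region.image
        w = np.where(msk, np.clip(sub - model.background_median, 0.0, None), 0.0)
        tot = w.sum()
        ys, xs = np.mgrid[r0:r1, c0:c1]
        if tot > 0:
            cy = float((w * ys).sum() / tot)
            cx = float((w * xs).sum() / tot)
        else:  # flat object: fall back to the unweighted pixel centroid
            cy = float(ys[msk].mean())
            cx = float(xs[msk].mean())
        objects.append(
            ObjectMask(
                tile_row=tile_row,
                tile_col=tile_col,
                bbox=(r0, c0, r1, c1),
                mask=msk.copy(),
                area_px=int(region.area),
                area_um2=float(area_um2),
                centroid_px=(cx, cy),
                pixel_pitch=pixel_pitch,
            )
        )
    objects.sort(key=lambda o: (o.bbox[0], o.bbox[1]))
    return objects


# ---------------------------------------------------------------------------
# per-object measurements
# ---------------------------------------------------------------------------


def _nuclear_labels(nuclear_plane: np.ndarray, nuclear_model: ThresholdModel) -> np.ndarray:
    supra = np.asarray(nuclear_plane, dtype=float) > nuclear_model.threshold
    return measure.label(supra, connectivity=2)


def nuclear_overlap(
    mask: ObjectMask, nuclear_plane: np.ndarray, nuclear_model: ThresholdModel
) -> float:
    """Fraction of the object's nuclei that lie inside the object mask.

    Nuclear supra-threshold pixels are grouped into connected components; the
    components that intersect the mask are taken to be the object's nuclei, and
    the returned value is |nuclei inside the mask| / |nuclei total| in pixels.
    A whole nucleus inside the object gives 1.0; no nuclear signal gives 0.0;
    a nucleus straddling the mask edge gives the contained fraction. The
    measure asks "does this object carry a nucleus", independently of how much
    cytoplasm surrounds it (the N:C ratio is a separate feature).
    """
    lbl = _nuclear_labels(nuclear_plane, nuclear_model)
    full = mask.full_mask(lbl.shape)
    ids = np.unique(lbl[full])
    ids = ids[ids != 0]
    if ids.size == 0:
        return 0.0
    member = np.isin(lbl, ids)
    inside = np.count_nonzero(member & full)
    total = np.count_nonzero(member)
    return float(inside) / float(total)


def nc_ratio(
    mask: ObjectMask, nuclear_plane: np.ndarray, nuclear_model: ThresholdModel
) -> float:
    """Nuclear-to-cytoplasm area ratio: nuclear supra-threshold pixels inside
    the mask divided by the mask area. Low for squamous contaminants, whose
    cytoplasm dwarfs the nucleus."""
    supra = np.asarray(nuclear_plane, dtype=float) > nuclear_model.threshold
    full = mask.full_mask(supra.shape)
    return float(np.count_nonzero(supra & full)) / float(mask.area_px)


def cd45_correlation(
    mask: ObjectMask,
    ck_plane: np.ndarray,
    cd45_plane: np.ndarray,
    dilate_px: int = 2,
) -> float:
    """Pearson correlation of CK vs CD45 over the object footprint.

    The footprint is the mask dilated by ``dilate_px`` so that membrane CD45
    ringing a CK-positive object is captured. If either channel is constant
    over the footprint the correlation is defined as 0.
    """
    full = mask.full_mask(np.asarray(ck_plane).shape)
    if dilate_px > 0:
        full = ndi.binary_dilation(full, structure=morphology.disk(dilate_px))
    a = np.asarray(ck_plane, dtype=float)[full]
    b = np.asarray(cd45_plane, dtype=float)[full]
    if a.size < 2 or a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class ObjectFeatures:
    """Per-object quantities consumed by the classifier."""

    means: Dict[str, float]
    maxes: Dict[str, float]
    area_um2: float
    equiv_diam_um: float
    nuclear_overlap_fraction: float
    cd45_correlation: float
    nc_ratio: float
    nuclear_components: int  # nuclei intersecting the object (cluster hint)


def extract_features(
    tile: TileImage,
    mask: ObjectMask,
    models: Dict[str, ThresholdModel],
    nuclear_channel: str = "nuclear",
    ck_channel: str = "ck",
    cd45_channel: str = "cd45",
) -> ObjectFeatures:
    """Measure one segmented object across all channels of a tile."""
    full = mask.full_mask(tile.shape)
    means, maxes = {}, {}
    for ch, plane in tile.planes.items():
        vals = np.asarray(plane, dtype=float)[full]
        means[ch] = float(vals.mean())
        maxes[ch] = float(vals.max())

    nuc_model = models[nuclear_channel]
    nuc_plane = tile.planes[nuclear_channel]
    lbl = _nuclear_labels(nuc_plane, nuc_model)
    ids = np.unique(lbl[full])
    ids = ids[ids != 0]

    return ObjectFeatures(
        means=means,
        maxes=maxes,
        area_um2=mask.area_um2,
        equiv_diam_um=2.0 * math.sqrt(mask.area_um2 / math.pi),
        nuclear_overlap_fraction=nuclear_overlap(mask, nuc_plane, nuc_model),
        cd45_correlation=cd45_correlation(
            mask, tile.planes[ck_channel], tile.planes[cd45_channel]
        ),
        nc_ratio=nc_ratio(mask, nuc_plane, nuc_model),
        nuclear_components=int(ids.size),
    )


# ---------------------------------------------------------------------------
# channel registration
# ---------------------------------------------------------------------------


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -1.0, 1.0))


def _xcorr_shift(reference: np.ndarray, moving: np.ndarray) -> Tuple[float, float]:
    """Displacement (dx, dy) such that ``moving ~= reference shifted by it``.

    FFT cross-correlation peak with per-axis parabolic sub-pixel refinement.
    """
    a = np.asarray(moving, dtype=float)
    b = np.asarray(reference, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    c = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
    peak = np.unravel_index(np.argmax(c), c.shape)
    h, w = c.shape
    py, px = int(peak[0]), int(peak[1])
    dy = _parabolic_offset(c[(py - 1) % h, px], c[py, px], c[(py + 1) % h, px])
    dx = _parabolic_offset(c[py, (px - 1) % w], c[py, px], c[py, (px + 1) % w])
    sy = py + dy
    sx = px + dx
    if sy > h / 2:
        sy -= h
    if sx > w / 2:
        sx -= w
    return (float(sx), float(sy))


def register_channels(
    calibration_tile: TileImage, reference_channel: str = "nuclear"
) -> Dict[str, Tuple[float, float]]:
    """Estimate per-channel chromatic displacement against a reference channel.

    Requires a calibration image with structure shared across channels (e.g. a
    bead field). Returns (dx, dy) per non-reference channel; applying the
    negated shift with :func:`rarescan.simslide.apply_chromatic_shift`
    co-registers the channels.
    """
    ref = np.asarray(calibration_tile.planes[reference_channel], dtype=float)
    if ref.std() == 0.0:
        raise CalibrationError(
            f"reference channel {reference_channel!r} is flat; cannot register"
        )
    shifts: Dict[str, Tuple[float, float]] = {}
    for ch, plane in calibration_tile.planes.items():
        if ch == reference_channel:
            continue
        mov = np.asarray(plane, dtype=float)
        if mov.std() == 0.0:
            raise CalibrationError(f"channel {ch!r} is flat; cannot register")
        shifts[ch] = _xcorr_shift(ref, mov)
    return shifts
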