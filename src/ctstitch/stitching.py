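"""Concatenation of overlapping micro-CT scan volumes with intensity equalisation.

When a specimen is taller than the cone-beam field of view it is scanned at
several overlapping vertical positions.  Joining the reconstructed stacks
needs three things: an XY translation bringing the stacks into register, a
*fusion slice* — the axial slice at which the bottom stack hands over to the
top stack — and an intensity calibration that removes the brightness drift
between scans caused by the X-ray tube's heel effect.

The pipeline implemented here mirrors a scriptable version of the
interactive workflow: optional landmark-based XY translation; fusion-slice
selection either manually or automatically, by z-score-normalising a
reference slice from the bottom stack and every slice of the top stack and
picking the top slice whose normalised residual has minimum standard
deviation (z-scoring makes the match invariant to exactly the affine
intensity distortions corrected later); a straight-line intensity fit of
paired ROI means on the matched slice pair; crop-and-concatenate fusion; and
a radial-reslice preview for judging seam smoothness.

Indexing is 0-based throughout this module; user-facing layers convert to
the 1-based slice numbering common in image viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Volume, round_half_away

__all__ = [
    "TranslationXY",
    "FusionSelection",
    "IntensityCalibration",
    "StitchResult",
    "StitchConfig",
    "translate_xy",
    "translation_from_landmarks",
    "select_fusion_slice_auto",
    "default_rois",
    "fit_intensity_calibration",
    "apply_intensity_calibration",
    "concatenate_pair",
    "stitch_many",
    "radial_reslice_preview",
    "check_bit_depths",
]


@dataclass(frozen=True)
class TranslationXY:
    """Integer pixel translation applied identically to every slice."""

    dy_px: int
    dx_px: int


@dataclass
class FusionSelection:
    """The chosen fusion slice on the bottom and top stacks.

    In auto mode ``score_profile[k]`` is the standard deviation of the
    residual between the z-scored top slice k and the z-scored reference
    slice; ``top_slice`` is the first argmin of that profile.  ``confidence``
    is the heuristic 1 - min/median of the profile, clamped to [0, 1] — near
    1 when one slice matches far better than the rest, near 0 when the
    profile is flat.
    """

    bottom_slice: int
    top_slice: int
    mode: str = "manual"
    score_profile: np.ndarray | None = None
    confidence: float = 1.0


@dataclass
class IntensityCalibration:
    """Straight-line map of top-stack intensities onto the bottom scale.

    ``output = slope * input + intercept``; fitted by ordinary least squares
    through paired ROI mean intensities sampled on the matched fusion slices.
    """

    slope: float
    intercept: float
    roi_means_bottom: list[float] = field(default_factory=list)
    roi_means_top: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.roi_means_bottom) != len(self.roi_means_top):
            raise ValueError("paired ROI mean lists must have equal length")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("calibration parameters must be finite")

    @property
    def n_rois(self) -> int:
        return len(self.roi_means_bottom)

    @classmethod
    def identity(cls) -> "IntensityCalibration":
        return cls(1.0, 0.0)


@dataclass
class StitchResult:
    """A fused volume plus full provenance of how it was assembled.

    ``provenance`` lists, per contributing scan, the half-open z range it
    occupies in the output and the fusion selection, intensity calibration
    and XY translation applied to it (None for the first scan).  The crop
    ranges tile the output z axis exactly.
    """

    volume: Volume
    provenance: list[dict]

    def __post_init__(self):
        stops = 0
        for entry in self.provenance:
            start, stop = entry["crop_range"]
            if start != stops or stop <= start:
                raise ValueError(
                    f"provenance crop ranges must tile the z axis; got {entry['crop_range']}"
                    f" after {stops}"
                )
            stops = stop
        if stops != self.volume.z_extent:
            raise ValueError(
                f"provenance covers [0, {stops}) but volume has {self.volume.z_extent} slices"
            )


def check_bit_depths(*volumes: Volume) -> None:
    """Refuse mixed bit depths before any computation."""
    depths = {v.bit_depth for v in volumes}
    if len(depths) > 1:
        raise ValueError(
            f"bit depths are different ({sorted(depths)}); convert stacks to a "
            "common depth before stitching"
        )


def translate_xy(volume: Volume, t: TranslationXY, fill: float = 0.0) -> Volume:
    """Shift every slice by (dy, dx) pixels, filling vacated borders.

    A landmark at (y, x) moves to (y + dy, x + dx); extents are unchanged.
    """
    dy, dx = int(t.dy_px), int(t.dx_px)
    _, Y, X = volume.shape
    if abs(dy) >= Y or abs(dx) >= X:
        raise ValueError(f"shift ({dy}, {dx}) not smaller than extents ({Y}, {X})")
    out = np.full_like(volume.voxels, fill)
    src_y = slice(max(0, -dy), Y - max(0, dy))
    src_x = slice(max(0, -dx), X - max(0, dx))
    dst_y = slice(max(0, dy), Y - max(0, -dy))
    dst_x = slice(max(0, dx), X - max(0, -dx))
    out[:, dst_y, dst_x] = volume.voxels[:, src_y, src_x]
    return Volume(out, volume.voxel_size_um, volume.bit_depth, volume.intensity_units)


def translation_from_landmarks(
    p_bottom: tuple[float, float],
    p_top: tuple[float, float],
    pixel_size_um: float | None = None,
) -> TranslationXY:
    """Translation mapping the top-stack landmark onto the bottom-stack one.

    If ``pixel_size_um`` is given the landmark coordinates are in physical
    units (µm) and the translation is converted to whole pixels with
    round-half-away-from-zero.
    """
    dy = p_bottom[0] - p_top[0]
    dx = p_bottom[1] - p_top[1]
    if pixel_size_um is not None:
        dy, dx = dy / pixel_size_um, dx / pixel_size_um
    return TranslationXY(int(round_half_away(dy)), int(round_half_away(dx)))


def _zscore(img: np.ndarray) -> np.ndarray:
    """Z-score a slice; a constant slice maps to all zeros."""
    img = img.astype(np.float64)
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def select_fusion_slice_auto(
    bottom: Volume, top: Volume, reference_index: int
) -> FusionSelection:
    """Find the top-stack slice depicting the same section as a bottom slice.

    The reference slice (bottom stack) and every top slice are z-scored;
    the score for top slice k is the standard deviation of the difference of
    the normalised images.  An exact copy scores 0; affine intensity changes
    (gain/offset) do not move the minimum.  Ties break to the lowest index.
    """
    if top.z_extent == 0:
        raise ValueError("top stack has no slices")
    if bottom.shape[1:] != top.shape[1:]:
        raise ValueError(
            f"XY extents differ: bottom {bottom.shape[1:]} vs top {top.shape[1:]}; "
            "translate into register first"
        )
    if not 0 <= reference_index < bottom.z_extent:
        raise IndexError(f"reference index {reference_index} outside bottom stack")
    ref = _zscore(bottom.voxels[reference_index])
    scores = np.empty(top.z_extent)
    for k in range(top.z_extent):
        scores[k] = (_zscore(top.voxels[k]) - ref).std()
    best = int(np.argmin(scores))
    med = float(np.median(scores))
    confidence = 0.0 if med == 0 else float(np.clip(1.0 - scores[best] / med, 0.0, 1.0))
    return FusionSelection(
        bottom_slice=reference_index,
        top_slice=best,
        mode="auto",
        score_profile=scores,
        confidence=confidence,
    )


def default_rois(
    shape: tuple[int, int],
    reference: np.ndarray | None = None,
    grid: int = 4,
    variance_floor: float = 0.0,
) -> list[tuple[int, int, int, int]]:
    """A ``grid`` x ``grid`` set of square patches over the central 80%.

    Rectangles are (y0, y1, x0, x1), half-open.  Patches whose variance on
    ``reference`` is at or below ``variance_floor`` (flat background) are
    dropped.
    """
    Y, X = shape
    y0, x0 = int(0.1 * Y), int(0.1 * X)
    span_y, span_x = Y - 2 * y0, X - 2 * x0
    side = max(1, min(span_y, span_x) // (2 * grid))
    rois = []
    for i in range(grid):
        for j in range(grid):
            cy = y0 + int((i + 0.5) * span_y / grid)
            cx = x0 + int((j + 0.5) * span_x / grid)
            rect = (cy - side // 2, cy - side // 2 + side,
                    cx - side // 2, cx - side // 2 + side)
            if reference is not None:
                patch = reference[rect[0] : rect[1], rect[2] : rect[3]]
                if patch.var() <= variance_floor:
                    continue
            rois.append(rect)
    return rois


def fit_intensity_calibration(
    bottom_fusion_slice: np.ndarray,
    top_fusion_slice: np.ndarray,
    rois: list[tuple[int, int, int, int]] | None = None,
) -> IntensityCalibration:
    """Fit the straight line mapping top intensities onto the bottom scale.

    Both images must depict the same physical section (the matched fusion
    slices).  ROI rectangles are (y0, y1, x0, x1); when omitted, a default
    grid over the central 80% of the slice is used with flat background
    patches dropped.  Ordinary least squares through the paired ROI means.
    """
    bottom_fusion_slice = np.asarray(bottom_fusion_slice, dtype=np.float64)
    top_fusion_slice = np.asarray(top_fusion_slice, dtype=np.float64)
    if bottom_fusion_slice.shape != top_fusion_slice.shape:
        raise ValueError("fusion slices must share shape")
    if rois is None:
        rois = default_rois(bottom_fusion_slice.shape, reference=bottom_fusion_slice)
    if len(rois) < 2:
        raise ValueError(f"need at least 2 ROIs for a line fit, got {len(rois)}")
    means_b, means_t = [], []
    Y, X = bottom_fusion_slice.shape
    for (r0, r1, c0, c1) in rois:
        if not (0 <= r0 < r1 <= Y and 0 <= c0 < c1 <= X):
            raise ValueError(f"ROI {(r0, r1, c0, c1)} outside image bounds {(Y, X)}")
        means_b.append(float(bottom_fusion_slice[r0:r1, c0:c1].mean()))
        means_t.append(float(top_fusion_slice[r0:r1, c0:c1].mean()))
    t = np.array(means_t)
    b = np.array(means_b)
    if np.ptp(t) == 0:
        raise ValueError("all top ROI means identical; line fit is degenerate")
    slope, intercept = np.polyfit(t, b, 1)
    return IntensityCalibration(float(slope), float(intercept), means_b, means_t)


def apply_intensity_calibration(volume: Volume, cal: IntensityCalibration) -> Volume:
    """Map every voxel v -> slope*v + intercept, in floating point."""
    out = cal.slope * volume.voxels.astype(np.float64) + cal.intercept
    return Volume(out, volume.voxel_size_um, bit_depth=32,
                  intensity_units=volume.intensity_units)


def concatenate_pair(
    bottom: Volume,
    top: Volume,
    fusion: FusionSelection,
    cal: IntensityCalibration | None = None,
    translation: TranslationXY | None = None,
    duplicate_fusion_slice: bool = False,
) -> StitchResult:
    """Crop, calibrate and join a bottom/top stack pair at the fusion slice.

    The bottom stack contributes slices 0..bottom_slice inclusive; the top
    stack contributes from top_slice + 1 onward (the fusion slice enters
    once, from the bottom stack).  Set ``duplicate_fusion_slice`` to let the
    top stack start at top_slice instead, duplicating the physical section.
    The top portion is intensity-calibrated before concatenation and the
    output is floating point; quantise only at write time.
    """
    check_bit_depths(bottom, top)
    if bottom.shape[1:] != top.shape[1:]:
        raise ValueError("XY extents differ; translate into register first")
    if not 0 <= fusion.bottom_slice < bottom.z_extent:
        raise IndexError(f"bottom fusion slice {fusion.bottom_slice} out of range")
    if not 0 <= fusion.top_slice < top.z_extent:
        raise IndexError(f"top fusion slice {fusion.top_slice} out of range")
    cal = cal or IntensityCalibration.identity()
    if translation is not None:
        top = translate_xy(top, translation, fill=float(top.voxels.min()))
    top_start = fusion.top_slice if duplicate_fusion_slice else fusion.top_slice + 1
    if top_start >= top.z_extent:
        warnings.warn(
            "fusion at the last top slice: the top stack contributes nothing",
            stacklevel=2,
        )
    bottom_part = bottom.voxels[: fusion.bottom_slice + 1].astype(np.float64)
    top_part = cal.slope * top.voxels[top_start:].astype(np.float64) + cal.intercept
    fused = np.concatenate([bottom_part, top_part])
    n_b = bottom_part.shape[0]
    provenance = [
        {"scan": 0, "crop_range": (0, n_b), "fusion": None, "calibration": None,
         "translation": None},
    ]
    if fused.shape[0] > n_b:
        provenance.append(
            {"scan": 1, "crop_range": (n_b, fused.shape[0]), "fusion": fusion,
             "calibration": cal, "translation": translation}
        )
    volume = Volume(fused, bottom.voxel_size_um, bit_depth=32,
                    intensity_units=bottom.intensity_units)
    return StitchResult(volume=volume, provenance=provenance)


@dataclass
class StitchConfig:
    """Options for :func:`stitch_many`.

    fusion_mode is "auto" (residual-minimising slice search) or "manual"
    (explicit (bottom, top) index pairs; the bottom index refers to the
    current working volume, i.e. everything concatenated so far, exactly as
    when the interactive workflow is repeated scan by scan).  For auto mode,
    ``reference_indices`` gives the bottom-stack reference slice per
    adjacent pair; by default the last slice of the current bottom volume
    minus ``reference_setback``.  Pairs whose selection confidence falls
    below ``min_confidence`` abort the stitch unless ``force``.
    """

    fusion_mode: str = "auto"
    reference_indices: list[int] | None = None
    reference_setback: int = 0
    manual_fusions: list[tuple[int, int]] | None = None
    translations: list[TranslationXY] | None = None
    rois: list[tuple[int, int, int, int]] | None = None
    calibrate: bool = True
    min_confidence: float = 0.0
    force: bool = False
    duplicate_fusion_slice: bool = False


def stitch_many(scans: list[Volume], config: StitchConfig | None = None) -> StitchResult:
    """Left fold of pairwise concatenation over an ordered scan list.

    All computation is in floating point; quantisation (8-bit conversion)
    is a separate, final step.  The provenance chain covers every scan with
    crop ranges tiling the output z axis.
    """
    config = config or StitchConfig()
    if len(scans) < 2:
        raise ValueError(f"stitching needs at least 2 scans, got {len(scans)}")
    check_bit_depths(*scans)
    n_pairs = len(scans) - 1
    if config.fusion_mode == "manual":
        if config.manual_fusions is None or len(config.manual_fusions) != n_pairs:
            raise ValueError(f"manual mode needs {n_pairs} (bottom, top) fusion pairs")
    elif config.fusion_mode != "auto":
        raise ValueError(f"unknown fusion mode {config.fusion_mode!r}")
    if config.translations is not None and len(config.translations) != n_pairs:
        raise ValueError(f"need {n_pairs} translations (one per adjacent pair)")

    current = scans[0].astype_float()
    provenance = [{"scan": 0, "crop_range": (0, current.z_extent), "fusion": None,
                   "calibration": None, "translation": None}]
    for i in range(1, len(scans)):
        top = scans[i].astype_float()
        translation = config.translations[i - 1] if config.translations else None
        if translation is not None:
            top = translate_xy(top, translation, fill=float(top.voxels.min()))
        if config.fusion_mode == "manual":
            b_idx, t_idx = config.manual_fusions[i - 1]
            fusion = FusionSelection(bottom_slice=b_idx, top_slice=t_idx, mode="manual")
        else:
            if config.reference_indices is not None:
                ref = config.reference_indices[i - 1]
            else:
                ref = current.z_extent - 1 - config.reference_setback
            fusion = select_fusion_slice_auto(current, top, ref)
            if fusion.confidence < config.min_confidence and not config.force:
                raise RuntimeError(
                    f"fusion confidence {fusion.confidence:.3f} for pair "
                    f"({i - 1}, {i}) below floor {config.min_confidence}; "
                    "use force to proceed"
                )
        if config.calibrate:
            cal = fit_intensity_calibration(
                current.voxels[fusion.bottom_slice],
                top.voxels[fusion.top_slice],
                rois=config.rois,
            )
        else:
            cal = IntensityCalibration.identity()
        result = concatenate_pair(
            current, top, fusion, cal,
            duplicate_fusion_slice=config.duplicate_fusion_slice,
        )
        cut = fusion.bottom_slice + 1
        kept = []
        for entry in provenance:
            start, stop = entry["crop_range"]
            if start >= cut:
                continue
            e = dict(entry)
            e["crop_range"] = (start, min(stop, cut))
            kept.append(e)
        if result.volume.z_extent > cut:
            kept.append({
                "scan": i,
                "crop_range": (cut, result.volume.z_extent),
                "fusion": fusion,
                "calibration": cal,
                "translation": translation,
            })
        provenance = kept
        current = result.volume
    return StitchResult(volume=current, provenance=provenance)


def radial_reslice_preview(
    volume: Volume,
    n_angles: int = 8,
    axis_centre: tuple[float, float] | None = None,
) -> np.ndarray:
    """Longitudinal sections along rays fanning out from a central axis.

    For each of ``n_angles`` evenly spaced angles a (z x radius) section is
    sampled by bilinear interpolation along the ray from ``axis_centre``
    (default: the XY centre) at that angle in every slice; the radius runs
    to the nearest image border.  Angle 0 points along +x and angles
    increase towards +y.  Returns an array (n_angles, z, radius); seam
    discontinuities in a stitched volume show up as horizontal bands.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    Z, Y, X = volume.shape
    if axis_centre is None:
        axis_centre = ((Y - 1) / 2.0, (X - 1) / 2.0)
    cy, cx = axis_centre
    if not (0 <= cy <= Y - 1 and 0 <= cx <= X - 1):
        raise ValueError(f"axis centre {axis_centre} outside XY bounds")
    n_r = int(min(cy, cx, Y - 1 - cy, X - 1 - cx)) + 1
    radii = np.arange(n_r, dtype=np.float64)
    zs = np.arange(Z, dtype=np.float64)
    out = np.empty((n_angles, Z, n_r))
    data = volume.voxels.astype(np.float64)
    for j in range(n_angles):
        theta = 2.0 * np.pi * j / n_angles
        ys = cy + radii * np.sin(theta)
        xs = cx + radii * np.cos(theta)
        zz, rr = np.meshgrid(zs, np.arange(n_r), indexing="ij")
        coords = np.stack([zz.ravel(), ys[rr.ravel()], xs[rr.ravel()]])
        out[j] = ndimage.map_coordinates(data, coords, order=1, mode="nearest").reshape(Z, n_r)
    return out
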