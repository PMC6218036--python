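"""Binary body-mask extraction from green-screen profile photographs.

The capture protocol assumes a standing subject photographed against a
uniform chroma-key green background, once from the back (arms and legs
separated) and once from the side (arms close to the body, legs together).
This module turns each photograph into a cleaned, vertically symmetrized
binary silhouette with a cm-per-pixel calibration derived from the
subject's measured height.

Coordinate convention: row 0 is the image top; points are (row, col),
0-based. Widths are measured in pixels and converted through
``scale_cm_per_px``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color, measure, transform

from .errors import EmptyMaskError, FramingError, ValidationError

#: Sentinel for "height not yet calibrated".
UNSET_SCALE = float("nan")

BACK = "back"
SIDE = "side"


@dataclass(frozen=True)
class ChromaKeyConfig:
    """Thresholds classifying background pixels by hue distance to green.

    HSV is used rather than raw RGB so the key tolerates uniform
    brightness shifts of the backdrop. ``hue_center`` and ``hue_tol`` are
    in skimage's [0, 1) hue units (green = 1/3); a pixel is background iff
    its circular hue distance to ``hue_center`` is at most ``hue_tol`` and
    its saturation is at least ``sat_min``.
    """

    hue_center: float = 1.0 / 3.0
    hue_tol: float = 0.10
    sat_min: float = 0.25
    #: Background holes smaller than this fraction of the foreground area
    #: are treated as clothing speckle and filled.
    min_hole_frac: float = 0.005
    #: Capture-protocol metadata, recorded but not enforced: the study
    #: standardized a 91 in camera-to-subject distance.
    camera_distance_in: float = 91.0


@dataclass(frozen=True)
class ProfileImage:
    """One RGB profile photograph of one subject."""

    pixels: np.ndarray  # rows x cols x 3, uint8
    profile: str  # BACK or SIDE
    subject_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError("pixels must be rows x cols x 3 RGB")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValidationError("image must be at least 64 x 64")
        if self.profile not in (BACK, SIDE):
            raise ValidationError(f"profile must be '{BACK}' or '{SIDE}'")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BodyMask:
    """Binary silhouette for one profile plus its calibration state."""

    mask: np.ndarray  # bool, rows x cols
    profile: str
    scale_cm_per_px: float = UNSET_SCALE
    rotation_applied_deg: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)

    @property
    def is_calibrated(self) -> bool:
        return not math.isnan(self.scale_cm_per_px)

    @property
    def foreground_rows(self) -> np.ndarray:
        return np.flatnonzero(self.mask.any(axis=1))

    @property
    def pixel_height(self) -> int:
        rows = self.foreground_rows
        if rows.size == 0:
            return 0
        return int(rows[-1] - rows[0] + 1)

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


def _hue_distance(hue: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(hue - center)
    return np.minimum(d, 1.0 - d)


def extract_mask(image: ProfileImage, config: ChromaKeyConfig | None = None) -> BodyMask:
    """Chroma-key the green background away and return a cleaned body mask.

    Keeps the largest 4-connected foreground component, fills background
    holes smaller than ``config.min_hole_frac`` of the foreground area
    (clothing speckle), and leaves the scale unset until
    :func:`normalize_height` is called.

    Raises
    ------
    EmptyMaskError
        If no foreground survives thresholding.
    FramingError
        If the silhouette touches both the top and bottom borders (subject
        not fully in frame) or either vertical border.
    """
    config = config or ChromaKeyConfig()
    hsv = color.rgb2hsv(image.pixels)
    background = (_hue_distance(hsv[..., 0], config.hue_center) <= config.hue_tol) & (
        hsv[..., 1] >= config.sat_min
    )
    fg = ~background
    if not fg.any():
        raise EmptyMaskError(f"no foreground pixels after chroma keying ({image.subject_id})")

    # Largest 4-connected component.
    labels = measure.label(fg, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == int(np.argmax(counts))

    # Fill only small background holes (clothing speckle); larger enclosed
    # holes indicate a capture problem and are left for downstream errors.
    holes = ndimage.binary_fill_holes(fg) & ~fg
    if holes.any():
        max_hole = config.min_hole_frac * int(fg.sum())
        hole_labels, n_holes = ndimage.label(holes)
        sizes = ndimage.sum_labels(np.ones_like(hole_labels), hole_labels, range(1, n_holes + 1))
        for i, size in enumerate(sizes, start=1):
            if size < max_hole:
                fg[hole_labels == i] = True

    if fg[0, :].any() and fg[-1, :].any():
        raise FramingError(f"subject touches top and bottom borders ({image.subject_id})")
    if fg[:, 0].any() or fg[:, -1].any():
        raise FramingError(f"subject touches a vertical border ({image.subject_id})")

    return BodyMask(mask=fg, profile=image.profile, subject_id=image.subject_id)


def _rotate(mask: np.ndarray, angle_deg: float, center: tuple[float, float]) -> np.ndarray:
    if angle_deg == 0.0:
        return mask
    out = transform.rotate(
        mask.astype(float), angle_deg, center=(center[1], center[0]), order=0, preserve_range=True
    )
    return out > 0.5

def _asymmetry(mask: np.ndarray) -> int:
    """XOR count between the mask and its mirror about the centroid column."""
    cc = np.nonzero(mask)[1]
    center = cc.mean()
    mirrored = np.fliplr(mask)
    # Mirroring about column `center` = fliplr then shift by 2*center-(W-1).
    shift = int(round(2.0 * center - (mask.shape[1] - 1)))
    mirrored = np.roll(mirrored, shift, axis=1)
    return int(np.count_nonzero(mask ^ mirrored))


def symmetrize(
    mask: BodyMask, search_deg: float = 15.0, resolution_deg: float = 0.1
) -> BodyMask:
    """Rotate the mask until it is left-right symmetric about the vertical.

    Minimizes the mirror-XOR asymmetry score over rotations in
    ``[-search_deg, +search_deg]`` about the foreground centroid, with a
    coarse 1 deg sweep refined to ``resolution_deg``. The applied angle is
    recorded in ``rotation_applied_deg``.
    """
    if not mask.mask.any():
        raise EmptyMaskError("cannot symmetrize an empty mask")
    center = mask.centroid

    def score(angle: float) -> int:
        return _asymmetry(_rotate(mask.mask, angle, center))

    coarse = np.arange(-search_deg, search_deg + 1e-9, 1.0)
    best = min(coarse, key=score)
    fine = np.arange(best - 1.0, best + 1.0 + 1e-9, resolution_deg)
    best = float(min(fine, key=score))
    rotated = _rotate(mask.mask, best, center)
    return replace(
        mask,
        mask=rotated,
        rotation_applied_deg=mask.rotation_applied_deg + best,
    )


def normalize_height(mask: BodyMask, true_height_cm: float) -> BodyMask:
    """Calibrate the mask against the subject's measured standing height.

    Sets ``scale_cm_per_px = true_height_cm / H_px`` where ``H_px`` is the
    foreground pixel height (bottom-most minus top-most foreground row
    plus one). The raster itself is untouched: this is a calibration, not
    a resampling.
    """
    if not (50.0 <= true_height_cm <= 250.0):
        raise ValidationError(f"true_height_cm={true_height_cm} outside plausible [50, 250] cm")
    h_px = mask.pixel_height
    if h_px == 0:
        raise EmptyMaskError("mask has no foreground; cannot normalize height")
    return replace(mask, scale_cm_per_px=true_height_cm / h_px)
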