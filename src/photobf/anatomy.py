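"""Landmark detection and body segmentation on the back-profile silhouette.

The back profile is taken with arms and legs separated, which creates
three deep concavities on the body contour: one armpit on each side and
the crotch. These *key points* anchor straight separation lines that
partition the silhouette into head, trunk, two arms and two legs. The
partition is exact: every foreground pixel is assigned to exactly one
component.

Armpits are located as the deepest convexity defects of the contour on
each side of the body; the crotch is the topmost background point of the
gap between the legs. The head/trunk split runs through the row of
minimal silhouette width in the upper quarter of the body (the neck).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .errors import DegenerateSegmentationError, PoseError
from .imaging import BACK, BodyMask

Point = tuple[int, int]  # (row, col)

HEAD = "head"
TRUNK = "trunk"
ARM_L = "arm_L"
ARM_R = "arm_R"
LEG_L = "leg_L"
LEG_R = "leg_R"
COMPONENTS = (HEAD, TRUNK, ARM_L, ARM_R, LEG_L, LEG_R)
LIMBS = (ARM_L, ARM_R, LEG_L, LEG_R)


@dataclass(frozen=True)
class KeyPoints:
    """Armpit, crotch and head-top landmarks on the back-profile mask."""

    left_upper: Point
    right_upper: Point
    lower: Point
    head_top: Point

    def __post_init__(self) -> None:
        if not self.left_upper[1] < self.right_upper[1]:
            raise PoseError("left armpit must be left of right armpit")
        if not self.lower[0] > max(self.left_upper[0], self.right_upper[0]):
            raise PoseError("crotch must lie below both armpits")
        if not self.head_top[0] < self.left_upper[0]:
            raise PoseError("head top must lie above the armpits")

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "left_upper": list(self.left_upper),
            "right_upper": list(self.right_upper),
            "lower": list(self.lower),
            "head_top": list(self.head_top),
        }


@dataclass(frozen=True)
class BodySegments:
    """Disjoint component masks whose union is the body mask."""

    component_masks: dict[str, np.ndarray]
    main_axis: dict[str, np.ndarray]  # unit (d_row, d_col) principal axis

    def areas(self) -> dict[str, int]:
        return {name: int(m.sum()) for name, m in self.component_masks.items()}


def _runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Foreground runs [(start, stop)) of a boolean row."""
    padded = np.diff(np.concatenate(([0], row.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def _convexity_defects(mask: np.ndarray, min_depth: float) -> list[tuple[float, float, float]]:
    """Deepest contour point under each convex-hull edge.

    Returns (row, col, depth) for every hull edge whose deepest interior
    contour point deviates from the chord by more than ``min_depth``
    pixels.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col) float, closed
    pts = contour[:-1]
    hull = ConvexHull(pts[:, ::-1])  # expects (x, y)
    hull_idx = np.sort(hull.vertices)
    defects = []
    n = len(pts)
    for a, b in zip(hull_idx, np.roll(hull_idx, -1)):
        if b > a:
            seg = np.arange(a, b + 1)
        else:  # wrap around the closed contour
            seg = np.concatenate([np.arange(a, n), np.arange(0, b + 1)])
        if len(seg) < 3:
            continue
        p0, p1 = pts[a], pts[b % n]
        chord = p1 - p0
        norm = np.hypot(*chord)
        if norm == 0:
            continue
        # Perpendicular distance of each in-between contour point to the chord.
        rel = pts[seg] - p0
        depth = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
        k = int(np.argmax(depth))
        if depth[k] > min_depth:
            r, c = pts[seg[k]]
            defects.append((float(r), float(c), float(depth[k])))
    return defects


def _crotch(mask: np.ndarray) -> Point:
    """Topmost background point of the between-legs gap."""
    rr, cc = np.nonzero(mask)
    center_col = cc.mean()
    bottom = rr.max()
    crotch = None
    for row in range(bottom, rr.min(), -1):
        runs = _runs(mask[row])
        gap = None
        for (_, e0), (s1, _) in zip(runs, runs[1:]):
            if e0 <= center_col <= s1:  # background gap straddling the body midline
                gap = (e0, s1)
                break
        if gap is not None:
            crotch = (row, int((gap[0] + gap[1] - 1) // 2))
        elif crotch is not None:
            break  # gap just closed: the previous row was its topmost point
    if crotch is None:
        raise PoseError("no background gap between the legs (legs not separated)")
    return crotch


def detect_key_points(mask: BodyMask, min_defect_depth_px: float | None = None) -> KeyPoints:
    """Find armpits, crotch, and head top on a back-profile mask.

    The armpit on each side is the deepest convexity defect of the body
    contour between the head top and the crotch; the pose (arms away from
    the trunk) guarantees this defect is far deeper than any neck or
    waist concavity.

    Raises
    ------
    PoseError
        If no between-legs gap exists or fewer than two armpit
        concavities are found.
    """
    if mask.profile != BACK:
        raise PoseError("key points are defined on the back profile only")
    m = mask.mask
    if not m.any():
        raise PoseError("empty mask")
    rr, cc = np.nonzero(m)
    top_row = int(rr.min())
    head_top = (top_row, int(round(np.mean(np.nonzero(m[top_row])[0]))))

    lower = _crotch(m)

    if min_defect_depth_px is None:
        min_defect_depth_px = max(5.0, 0.02 * mask.pixel_height)
    center_col = cc.mean()
    # Armpits lie far off the body midline (roughly at shoulder half-width);
    # midline concavities (neck, crotch) are rejected by a lateral gate at
    # a quarter of the body's half-span.
    min_lateral = 0.25 * (cc.max() - cc.min()) / 2.0
    defects = [
        d
        for d in _convexity_defects(m, min_defect_depth_px)
        if head_top[0] < d[0] < lower[0] and abs(d[1] - center_col) >= min_lateral
    ]
    left = [d for d in defects if d[1] < center_col]
    right = [d for d in defects if d[1] >= center_col]
    if not left or not right:
        raise PoseError("fewer than two armpit concavities (arms not separated from trunk)")
    lr, lc, _ = max(left, key=lambda d: d[2])
    rr_, rc, _ = max(right, key=lambda d: d[2])
    return KeyPoints(
        left_upper=(int(round(lr)), int(round(lc))),
        right_upper=(int(round(rr_)), int(round(rc))),
        lower=lower,
        head_top=head_top,
    )


def _principal_axis(component: np.ndarray) -> np.ndarray:
    coords = np.column_stack(np.nonzero(component)).astype(float)
    coords -= coords.mean(axis=0)
    if len(coords) < 2:
        return np.array([1.0, 0.0])
    cov = coords.T @ coords / len(coords)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, int(np.argmax(vals))]
    if axis[0] < 0:  # orient downward (increasing row)
        axis = -axis
    return axis


def segment_body(mask: BodyMask, kp: KeyPoints) -> BodySegments:
    """Partition the back silhouette into six components by straight lines.

    Arms: foreground strictly outside the vertical lines through the
    armpit key points, at or below armpit level. Legs: remaining
    foreground below the crotch, split at the crotch column. Head: above
    the neck line (row of minimal width in the upper quarter of body
    height). Trunk: everything else. Pixel conservation is exact.
    """
    m = mask.mask
    rows_idx, cols_idx = np.indices(m.shape)

    arm_l = m & (cols_idx < kp.left_upper[1]) & (rows_idx >= kp.left_upper[0])
    arm_r = m & (cols_idx > kp.right_upper[1]) & (rows_idx >= kp.right_upper[0])
    rest = m & ~arm_l & ~arm_r

    below_crotch = rest & (rows_idx > kp.lower[0])
    leg_l = below_crotch & (cols_idx <= kp.lower[1])
    leg_r = below_crotch & (cols_idx > kp.lower[1])
    rest = rest & ~below_crotch

    # Neck line: minimal silhouette width in the upper 25% of body height,
    # searched above the armpits. The top 5% of body height is excluded so
    # the narrow crown of the head cannot masquerade as the neck.
    h_px = mask.pixel_height
    top = kp.head_top[0]
    start = top + max(2, int(round(0.05 * h_px)))
    limit = min(top + max(3, int(0.25 * h_px)), min(kp.left_upper[0], kp.right_upper[0]))
    widths = m[start:limit].sum(axis=1)
    if widths.size == 0:
        raise DegenerateSegmentationError("no rows available for the neck line")
    neck_row = start + int(np.argmin(widths))
    head = rest & (rows_idx < neck_row)
    trunk = rest & ~head

    masks = {HEAD: head, TRUNK: trunk, ARM_L: arm_l, ARM_R: arm_r, LEG_L: leg_l, LEG_R: leg_r}
    for name, comp in masks.items():
        if not comp.any():
            raise DegenerateSegmentationError(f"component '{name}' is empty")
    axes = {name: _principal_axis(comp) for name, comp in masks.items()}
    return BodySegments(component_masks=masks, main_axis=axes)
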