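"""Trunk shape descriptors: front curve, side curve, and cluster encoding.

Fat distribution in the trunk is summarized by two 12-point curves
sampled at equally spaced rows between the left armpit key point and the
crotch key point:

* **FC (front curve)** — trunk silhouette width (cm) in the back
  profile at each of the 12 rows.
* **SC (side curve)** — signed horizontal distance (cm) from the side
  silhouette's back edge to the central bodyline (CBL), the vertical
  line dropped from the top of the head. Distances toward the subject's
  back are positive.

Cohorts of curves are clustered with K-means, with the number of
clusters k chosen in {2..10} by the Calinski-Harabasz criterion; each
subject's shape is then the one-hot vector of its nearest-centroid
cluster. FC and SC are always clustered separately, in cm, without
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .anatomy import KeyPoints
from .errors import InsufficientSampleError, ResolutionError, ValidationError
from .imaging import BodyMask

N_CURVE_POINTS = 12
K_RANGE = range(2, 11)


@dataclass(frozen=True)
class ShapeCurves:
    """12-point front and side trunk curves for one subject."""

    fc: np.ndarray  # cm, > 0
    sc: np.ndarray  # cm, signed (positive toward the back)
    trunk_span: tuple[int, int]  # (top_row, bottom_row) on the back mask

    def __post_init__(self) -> None:
        fc = np.asarray(self.fc, dtype=float)
        sc = np.asarray(self.sc, dtype=float)
        if fc.shape != (N_CURVE_POINTS,) or sc.shape != (N_CURVE_POINTS,):
            raise ValidationError("fc and sc must each have exactly 12 values")
        if not (fc > 0).all():
            raise ValidationError("front-curve widths must be positive")
        object.__setattr__(self, "fc", fc)
        object.__setattr__(self, "sc", sc)


def extract_curves(
    back_mask: BodyMask,
    side_mask: BodyMask,
    kp: KeyPoints,
    facing: str = "left",
) -> ShapeCurves:
    """Sample the 12-point front and side curves of the trunk.

    Rows are linspace-inclusive between the left armpit row and the
    crotch row. FC is the back-profile foreground width restricted to
    the trunk columns (between the armpit separation lines). SC is
    measured on the side profile at the same normalized heights, from
    the back edge of the silhouette to the CBL; ``facing`` states which
    way the subject faces in the side photograph (back edge on the
    opposite side).
    """
    sb, ss = back_mask.scale_cm_per_px, side_mask.scale_cm_per_px
    if np.isnan(sb) or np.isnan(ss):
        raise ValidationError("masks must be height-normalized before curve extraction")
    top, bottom = kp.left_upper[0], kp.lower[0]
    if bottom - top < 2 * N_CURVE_POINTS:
        raise ResolutionError("trunk span under 24 px; image resolution too coarse")
    rows = np.round(np.linspace(top, bottom, N_CURVE_POINTS)).astype(int)

    trunk_cols = slice(kp.left_upper[1], kp.right_upper[1] + 1)
    fc = back_mask.mask[rows, trunk_cols].sum(axis=1).astype(float) * sb

    # CBL on the side profile: vertical line through the top of the head.
    side = side_mask.mask
    side_rows_all = np.flatnonzero(side.any(axis=1))
    side_top = int(side_rows_all[0])
    cbl_col = float(np.mean(np.nonzero(side[side_top])[0]))
    back_top = int(back_mask.foreground_rows[0])
    side_rows = side_top + np.round((rows - back_top) * sb / ss).astype(int)
    side_rows = np.clip(side_rows, 0, side.shape[0] - 1)

    sc = np.empty(N_CURVE_POINTS)
    for i, r in enumerate(side_rows):
        cols = np.nonzero(side[r])[0]
        if cols.size == 0:
            raise ResolutionError(f"side silhouette empty at sampled row {r}")
        back_edge = cols.max() if facing == "left" else cols.min()
        sc[i] = (back_edge - cbl_col) * ss if facing == "left" else (cbl_col - back_edge) * ss
    return ShapeCurves(fc=fc, sc=sc, trunk_span=(int(top), int(bottom)))


@dataclass(frozen=True)
class CurveClustering:
    """Fitted K-means model for one curve family (FC or SC)."""

    k: int
    centroids: np.ndarray  # k x 12
    criterion_scores: dict[int, float]
    labels: np.ndarray  # training assignments
    seed: int


@dataclass(frozen=True)
class ShapeClusterModel:
    fc: CurveClustering
    sc: CurveClustering

    @property
    def k_fc(self) -> int:
        return self.fc.k

    @property
    def k_sc(self) -> int:
        return self.sc.k


@dataclass(frozen=True)
class BSEncoding:
    """One-hot cluster membership for FC and SC (the BS_PHOTO feature)."""

    fc_onehot: np.ndarray
    sc_onehot: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.fc_onehot, self.sc_onehot])


def _fit_one(curves: np.ndarray, seed: int, n_init: int = 10) -> CurveClustering:
    n = len(curves)
    scores: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in K_RANGE:
        if k >= n:
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(curves)
        scores[k] = float(calinski_harabasz_score(curves, labels))
        fits[k] = km
    best_k = max(scores, key=lambda k: scores[k])
    km = fits[best_k]
    return CurveClustering(
        k=best_k,
        centroids=km.cluster_centers_.copy(),
        criterion_scores=scores,
        labels=km.labels_.copy(),
        seed=seed,
    )


def fit_shape_clusters(curves: list[ShapeCurves], seed: int) -> ShapeClusterModel:
    """Cluster training FC and SC curves; pick k by Calinski-Harabasz.

    K-means with 10 random restarts is fit independently for each k in
    2..10 and each curve family; k* maximizes the Calinski-Harabasz
    score. Deterministic for a fixed seed.
    """
    if len(curves) <= 10:
        raise InsufficientSampleError("shape clustering requires more than 10 subjects")
    fc = np.vstack([c.fc for c in curves])
    sc = np.vstack([c.sc for c in curves])
    return ShapeClusterModel(fc=_fit_one(fc, seed), sc=_fit_one(sc, seed))


def _nearest(centroids: np.ndarray, x: np.ndarray) -> int:
    d = np.linalg.norm(centroids - x[None, :], axis=1)
    return int(np.argmin(d))  # argmin breaks ties toward the lowest index


def encode_shape(curves: ShapeCurves, model: ShapeClusterModel) -> BSEncoding:
    """One-hot encode a subject by its nearest FC and SC centroids."""
    if not (np.isfinite(curves.fc).all() and np.isfinite(curves.sc).all()):
        raise ValidationError("curve values must be finite")
    fc_onehot = np.zeros(model.k_fc)
    fc_onehot[_nearest(model.fc.centroids, curves.fc)] = 1.0
    sc_onehot = np.zeros(model.k_sc)
    sc_onehot[_nearest(model.sc.centroids, curves.sc)] = 1.0
    return BSEncoding(fc_onehot=fc_onehot, sc_onehot=sc_onehot)
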