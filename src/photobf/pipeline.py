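"""End-to-end feature extraction: photographs in, BV_PHOTO and curves out.

Chains the stages — chroma keying, symmetrization, height calibration,
key-point detection, segmentation, volume reconstruction, curve
extraction — for one subject or a whole cohort, attaching the stage name
and subject id to any failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anatomy, imaging, shape, volume
from .errors import PhotoBFError
from .imaging import BodyMask, ChromaKeyConfig, ProfileImage
from .model import SubjectRecord


@dataclass(frozen=True)
class PipelineConfig:
    chroma: ChromaKeyConfig = field(default_factory=ChromaKeyConfig)
    #: Which way the subject faces in the side photograph (the back edge
    #: of the silhouette is on the opposite side).
    facing: str = "left"
    symmetrize: bool = True
    rasterized_slices: bool = False


@dataclass(frozen=True)
class SubjectFeatures:
    """Photographic features for one subject, plus QC breadcrumbs."""

    subject_id: str
    bv_photo_L: float
    per_component_volume_L: dict[str, float]
    curves: shape.ShapeCurves
    key_points: anatomy.KeyPoints
    rotation_back_deg: float
    rotation_side_deg: float
    #: Raw silhouette pixel count (back + side), the resolution-dependent
    #: "photographic volume in megapixels" surrogate some reports use.
    silhouette_area_px: int = 0

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "bv_photo_L": self.bv_photo_L,
            "silhouette_area_Mpx": self.silhouette_area_px / 1e6,
            "per_component_volume_L": self.per_component_volume_L,
            "fc": self.curves.fc.tolist(),
            "sc": self.curves.sc.tolist(),
            "key_points": self.key_points.as_dict(),
            "qc": {
                "rotation_back_deg": self.rotation_back_deg,
                "rotation_side_deg": self.rotation_side_deg,
            },
        }


class StageError(PhotoBFError):
    """Wraps a stage failure with the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"[{stage}] {subject_id}: {cause}")
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause


def _prepare_mask(
    image: ProfileImage, height_cm: float, config: PipelineConfig
) -> BodyMask:
    mask = imaging.extract_mask(image, config.chroma)
    if config.symmetrize:
        mask = imaging.symmetrize(mask)
    return imaging.normalize_height(mask, height_cm)


def process_subject(
    back_image: ProfileImage,
    side_image: ProfileImage,
    height_cm: float,
    config: PipelineConfig | None = None,
) -> SubjectFeatures:
    """Run the full imaging chain for one subject."""
    config = config or PipelineConfig()
    sid = back_image.subject_id
    try:
        back = _prepare_mask(back_image, height_cm, config)
        side = _prepare_mask(side_image, height_cm, config)
    except PhotoBFError as e:
        raise StageError("imaging", sid, e) from e
    try:
        kp = anatomy.detect_key_points(back)
        segments = anatomy.segment_body(back, kp)
    except PhotoBFError as e:
        raise StageError("anatomy", sid, e) from e
    try:
        stack = volume.body_volume(segments, back, side, rasterized=config.rasterized_slices)
    except PhotoBFError as e:
        raise StageError("volume", sid, e) from e
    try:
        curves = shape.extract_curves(back, side, kp, facing=config.facing)
    except PhotoBFError as e:
        raise StageError("shape", sid, e) from e
    return SubjectFeatures(
        subject_id=sid,
        bv_photo_L=stack.total_volume_L,
        per_component_volume_L=stack.per_component_volume_L,
        curves=curves,
        key_points=kp,
        rotation_back_deg=back.rotation_applied_deg,
        rotation_side_deg=side.rotation_applied_deg,
        silhouette_area_px=int(back.mask.sum()) + int(side.mask.sum()),
    )


def records_from_synthetic(subjects, config: PipelineConfig | None = None) -> list[SubjectRecord]:
    """Run the pipeline over generated subjects and build model records."""
    records = []
    for s in subjects:
        feats = process_subject(s.phantom.back, s.phantom.side, s.height_cm, config)
        records.append(
            SubjectRecord(
                subject_id=s.subject_id,
                age=s.age, sex=s.sex, race=s.race,
                height_cm=s.height_cm, weight_kg=s.weight_kg, bmi=s.bmi,
                bf_dxa_pct=s.bf_dxa_pct,
                bv_photo_L=feats.bv_photo_L,
                curves=feats.curves,
            )
        )
    return records


def records_from_feature_table(df) -> list[SubjectRecord]:
    """Rebuild records from a features CSV (cohort columns + bv + fc/sc)."""
    records = []
    for _, row in df.iterrows():
        fc = np.array([row[f"fc_{i}"] for i in range(1, 13)], dtype=float)
        sc = np.array([row[f"sc_{i}"] for i in range(1, 13)], dtype=float)
        curves = shape.ShapeCurves(fc=fc, sc=sc, trunk_span=(0, 0))
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]), sex=int(row["sex"]), race=int(row["race"]),
                height_cm=float(row["height_cm"]), weight_kg=float(row["weight_kg"]),
                bmi=float(row["bmi"]), bf_dxa_pct=float(row["bf_dxa_pct"]),
                bv_photo_L=float(row["bv_photo_L"]),
                curves=curves,
            )
        )
    return records


def feature_table(records: list[SubjectRecord]):
    """Records as a flat DataFrame (cohort columns + bv_photo_L + fc/sc)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "age": r.age, "sex": r.sex, "race": r.race,
            "height_cm": r.height_cm, "weight_kg": r.weight_kg, "bmi": r.bmi,
            "bf_dxa_pct": r.bf_dxa_pct, "bv_photo_L": r.bv_photo_L,
        }
        for i in range(12):
            row[f"fc_{i + 1}"] = r.curves.fc[i]
            row[f"sc_{i + 1}"] = r.curves.sc[i]
        rows.append(row)
    return pd.DataFrame(rows)
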