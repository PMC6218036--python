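"""Parametric humanoid phantoms and synthetic cohorts with known truth.

The study's photographs are not deposited, so validation runs on
stylized phantoms: geometric solids (sphere head, circular neck,
elliptic trunk with piecewise-linear taper, circular-section arms and
legs) rendered as green-screen back/side profile pairs in the capture
pose (arms and legs separated in back view, arms close and legs together
in side view). Each phantom's exact volume is the sum of closed-form
primitive volumes, and its armpit/crotch/head-top landmarks are emitted
as ground truth, so the whole pipeline can be checked end to end.

Synthetic cohorts sample realistic anthropometry (heights, BMI, age, sex
and race frequencies mirroring a mixed community sample of children and
adults), realize each subject physically as a phantom whose widths are
solved so the body volume matches weight at a plausible tissue density,
and assign %BF by a declared generative model:

    %BF = b0 + b1*(BV/height_m) + b2*BMI + b3*female + b4*shape_class + N(0, sd)

where ``shape_class`` indexes discrete trunk-taper archetypes (uniform,
android/central, gynoid/hip) that alter the trunk curves at fixed
volume — a planted fat-distribution signal beyond BMI and volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ResolutionError, ValidationError
from .imaging import BACK, SIDE, ProfileImage

GREEN = np.array([0, 200, 0], dtype=np.uint8)
BODY = np.array([25, 25, 25], dtype=np.uint8)

#: How far (cm) the arm's wedge apex is embedded into the trunk so the
#: rasterized arm stays 4-connected to the body at any render scale.
ARM_OVERLAP_CM = 1.0

#: Trunk-taper archetypes: multipliers on (top, mid, bottom) widths for the
#: back and side profiles. Back multipliers never exceed 1 so the shoulders
#: stay the widest trunk row (the armpit separation lines then cut no trunk
#: flesh into the arms).
SHAPE_ARCHETYPES = {
    0: {"name": "uniform", "back": (1.0, 0.88, 0.82), "side": (1.0, 0.95, 0.90)},
    1: {"name": "android", "back": (1.0, 0.97, 0.80), "side": (1.0, 1.15, 0.85)},
    2: {"name": "gynoid", "back": (1.0, 0.85, 0.98), "side": (1.0, 0.90, 1.00)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions (cm) of one humanoid phantom.

    The trunk width profiles are piecewise linear with a breakpoint at
    mid-trunk; ``arm_width_cm`` is the arm's thickness perpendicular to
    its axis; ``arm_angle_deg`` is the outward tilt from vertical. Leg
    length is whatever remains of the standing height.
    """

    height_cm: float = 170.0
    head_radius_cm: float = 11.0
    neck_width_cm: float = 10.0
    neck_len_cm: float = 6.0
    trunk_len_cm: float = 54.0
    trunk_back_widths_cm: tuple[float, float, float] = (39.0, 34.3, 32.0)
    trunk_side_widths_cm: tuple[float, float, float] = (22.0, 20.9, 19.8)
    arm_width_cm: float = 8.5
    arm_len_cm: float = 52.0
    arm_angle_deg: float = 25.0
    leg_width_cm: float = 12.5
    leg_gap_cm: float = 7.0
    scale_cm_per_px: float = 0.5
    margin_cm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        dims = [
            self.height_cm, self.head_radius_cm, self.neck_width_cm, self.neck_len_cm,
            self.trunk_len_cm, *self.trunk_back_widths_cm, *self.trunk_side_widths_cm,
            self.arm_width_cm, self.arm_len_cm, self.leg_width_cm, self.leg_gap_cm,
            self.scale_cm_per_px,
        ]
        if any(d <= 0 for d in dims):
            raise ValidationError("all phantom dimensions must be positive")
        if self.leg_len_cm <= 0:
            raise ValidationError("height too small for the head/neck/trunk lengths")

    # -- derived geometry (cm, y measured down from the head top) --------
    @property
    def leg_len_cm(self) -> float:
        return self.height_cm - (2 * self.head_radius_cm + self.neck_len_cm + self.trunk_len_cm)

    @property
    def shoulder_y(self) -> float:
        return 2 * self.head_radius_cm + self.neck_len_cm

    @property
    def crotch_y(self) -> float:
        return self.shoulder_y + self.trunk_len_cm

    def trunk_width_at(self, y: float, profile: str) -> float:
        """Piecewise-linear trunk width at depth y below the head top."""
        w = self.trunk_back_widths_cm if profile == BACK else self.trunk_side_widths_cm
        t = (y - self.shoulder_y) / self.trunk_len_cm
        if t <= 0.5:
            return w[0] + (w[1] - w[0]) * (t / 0.5)
        return w[1] + (w[2] - w[1]) * ((t - 0.5) / 0.5)

    # -- closed-form volumes ---------------------------------------------
    def analytic_volumes_L(self) -> dict[str, float]:
        """Exact primitive volumes in liters (junction slivers neglected)."""
        head = 4.0 / 3.0 * math.pi * self.head_radius_cm**3
        neck = math.pi / 4.0 * self.neck_width_cm**2 * self.neck_len_cm
        trunk = 0.0
        wb, ws = self.trunk_back_widths_cm, self.trunk_side_widths_cm
        half = self.trunk_len_cm / 2.0
        for (b0, b1), (s0, s1) in (((wb[0], wb[1]), (ws[0], ws[1])), ((wb[1], wb[2]), (ws[1], ws[2]))):
            db, ds = (b1 - b0) / half, (s1 - s0) / half
            trunk += (math.pi / 4.0) * (
                b0 * s0 * half + (b0 * ds + db * s0) * half**2 / 2.0 + db * ds * half**3 / 3.0
            )
        arm = math.pi / 4.0 * self.arm_width_cm**2 * self.arm_len_cm
        leg = math.pi / 4.0 * self.leg_width_cm**2 * self.leg_len_cm
        return {
            "head": head / 1000.0,
            "neck": neck / 1000.0,
            "trunk": trunk / 1000.0,
            "arms": 2 * arm / 1000.0,
            "legs": 2 * leg / 1000.0,
        }

    @property
    def analytic_volume_L(self) -> float:
        return sum(self.analytic_volumes_L().values())


@dataclass(frozen=True)
class RenderedPhantom:
    back: ProfileImage
    side: ProfileImage
    analytic_volume_L: float
    landmarks: dict[str, tuple[int, int]]  # (row, col) pixel ground truth
    label_map: np.ndarray  # back-profile component codes
    spec: PhantomSpec


LABELS = {"head": 1, "neck": 2, "trunk": 3, "arm_L": 4, "arm_R": 5, "leg_L": 6, "leg_R": 7}


def _canvas(spec: PhantomSpec, half_span_cm: float) -> tuple[np.ndarray, np.ndarray, float]:
    s = spec.scale_cm_per_px
    h_cm = spec.height_cm + 2 * spec.margin_cm
    w_cm = 2 * (half_span_cm + spec.margin_cm)
    n_rows, n_cols = int(math.ceil(h_cm / s)), int(math.ceil(w_cm / s))
    y = (np.arange(n_rows) + 0.5) * s - spec.margin_cm  # cm below head top
    x = (np.arange(n_cols) + 0.5) * s - w_cm / 2.0  # cm from body midline
    return y, x, w_cm / 2.0


def render_phantom(spec: PhantomSpec) -> RenderedPhantom:
    """Render the back/side green-screen pair with ground truth attached.

    Raises :class:`ResolutionError` if the render scale is coarser than
    1 px per 2 cm.
    """
    if spec.scale_cm_per_px > 2.0:
        raise ResolutionError("render scale coarser than 1 px per 2 cm")
    s = spec.scale_cm_per_px
    theta = math.radians(spec.arm_angle_deg)
    arm_drop = spec.arm_len_cm * math.cos(theta)  # vertical extent of the arm
    arm_run = spec.arm_width_cm / math.cos(theta)  # horizontal width per row
    half_span = (
        spec.trunk_back_widths_cm[0] / 2.0 + spec.arm_len_cm * math.sin(theta) + arm_run + 2.0
    )

    # ---- back profile ---------------------------------------------------
    y, x, cx_cm = _canvas(spec, half_span)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    labels = np.zeros(yy.shape, dtype=np.uint8)

    r = spec.head_radius_cm
    labels[(xx**2 + (yy - r) ** 2) <= r**2] = LABELS["head"]
    labels[(np.abs(xx) <= spec.neck_width_cm / 2) & (yy >= 2 * r) & (yy < spec.shoulder_y)] = (
        LABELS["neck"]
    )
    in_trunk = (yy >= spec.shoulder_y) & (yy < spec.crotch_y)
    wb = np.array([spec.trunk_width_at(v, BACK) if spec.shoulder_y <= v < spec.crotch_y else 0.0 for v in y])
    labels[in_trunk & (np.abs(xx) <= wb[:, None] / 2)] = LABELS["trunk"]

    # Arms: sheared bands whose apex is embedded ARM_OVERLAP_CM into the
    # trunk so the rasterized arm is always 4-connected to the body; the
    # trunk keeps its pixels (arms drawn on background only).
    shoulder_half = spec.trunk_back_widths_cm[0] / 2.0
    in_arm_rows = (yy >= spec.shoulder_y) & (yy < spec.shoulder_y + arm_drop)
    inner = shoulder_half - ARM_OVERLAP_CM + (yy - spec.shoulder_y) * math.tan(theta)
    bg = labels == 0
    labels[bg & in_arm_rows & (-xx >= inner) & (-xx < inner + arm_run)] = LABELS["arm_L"]
    labels[bg & in_arm_rows & (xx >= inner) & (xx < inner + arm_run)] = LABELS["arm_R"]

    # Ground-truth labels follow the anatomical separation-line convention:
    # the shoulder cap above the armpit apex (and anything inside the
    # vertical armpit lines) belongs to the trunk.
    taper = (spec.trunk_back_widths_cm[0] - spec.trunk_back_widths_cm[1]) / spec.trunk_len_cm
    y_apex = spec.shoulder_y + ARM_OVERLAP_CM / (math.tan(theta) + taper)
    apex_half = spec.trunk_width_at(y_apex, BACK) / 2.0
    is_arm = (labels == LABELS["arm_L"]) | (labels == LABELS["arm_R"])
    labels[is_arm & ((yy < y_apex) | (np.abs(xx) <= apex_half))] = LABELS["trunk"]

    in_legs = (yy >= spec.crotch_y) & (yy < spec.crotch_y + spec.leg_len_cm)
    g = spec.leg_gap_cm / 2.0
    leg_band = (np.abs(xx) >= g) & (np.abs(xx) < g + spec.leg_width_cm)
    labels[in_legs & leg_band & (xx < 0)] = LABELS["leg_L"]
    labels[in_legs & leg_band & (xx > 0)] = LABELS["leg_R"]

    back_px = np.where((labels > 0)[..., None], BODY, GREEN).astype(np.uint8)

    # ---- side profile ---------------------------------------------------
    ys, xs, _ = _canvas(spec, spec.trunk_side_widths_cm[0] / 2.0 + 4.0)
    yy2, xx2 = np.meshgrid(ys, xs, indexing="ij")
    side_mask = (xx2**2 + (yy2 - r) ** 2) <= r**2
    side_mask |= (np.abs(xx2) <= spec.neck_width_cm / 2) & (yy2 >= 2 * r) & (yy2 < spec.shoulder_y)
    ws = np.array([spec.trunk_width_at(v, SIDE) if spec.shoulder_y <= v < spec.crotch_y else 0.0 for v in ys])
    side_mask |= (yy2 >= spec.shoulder_y) & (yy2 < spec.crotch_y) & (np.abs(xx2) <= ws[:, None] / 2)
    side_mask |= (
        (yy2 >= spec.crotch_y)
        & (yy2 < spec.crotch_y + spec.leg_len_cm)
        & (np.abs(xx2) <= spec.leg_width_cm / 2)
    )
    side_px = np.where(side_mask[..., None], BODY, GREEN).astype(np.uint8)

    def to_px(y_cm: float, x_cm: float) -> tuple[int, int]:
        return (
            int((y_cm + spec.margin_cm) / s),
            int((x_cm + cx_cm) / s),
        )

    # Armpit ground truth: the apex of the arm-trunk wedge, i.e. the depth
    # at which the arm's inner edge (starting ARM_OVERLAP_CM inside the
    # trunk) clears the tapering trunk edge.
    taper = (spec.trunk_back_widths_cm[0] - spec.trunk_back_widths_cm[1]) / spec.trunk_len_cm
    open_rate = math.tan(theta) + taper
    y_apex = spec.shoulder_y + ARM_OVERLAP_CM / open_rate
    apex_half = spec.trunk_width_at(y_apex, BACK) / 2.0
    landmarks = {
        "head_top": to_px(0.0, 0.0),
        "left_upper": to_px(y_apex, -apex_half),
        "right_upper": to_px(y_apex, apex_half),
        "lower": to_px(spec.crotch_y, 0.0),
    }
    sid = f"phantom-{spec.seed}"
    return RenderedPhantom(
        back=ProfileImage(pixels=back_px, profile=BACK, subject_id=sid),
        side=ProfileImage(pixels=side_px, profile=SIDE, subject_id=sid),
        analytic_volume_L=spec.analytic_volume_L,
        landmarks=landmarks,
        label_map=labels,
        spec=spec,
    )


def random_phantom(rng: np.random.Generator, scale_cm_per_px: float = 0.5) -> PhantomSpec:
    """Sample a plausible adult phantom with jittered proportions."""
    h = float(rng.uniform(150, 192))
    jit = lambda v, lo=0.9, hi=1.1: float(v * rng.uniform(lo, hi))
    wb_top = jit(0.225 * h)
    ws_top = jit(0.128 * h)
    back_m = rng.uniform(0.82, 0.98, size=2)
    side_m = rng.uniform(0.85, 1.1, size=2)
    return PhantomSpec(
        height_cm=h,
        head_radius_cm=jit(0.064 * h),
        neck_width_cm=jit(0.055 * h),
        neck_len_cm=jit(0.035 * h),
        trunk_len_cm=jit(0.31 * h),
        trunk_back_widths_cm=(wb_top, wb_top * float(back_m[0]), wb_top * float(back_m[1])),
        trunk_side_widths_cm=(ws_top, ws_top * float(side_m[0]), ws_top * float(side_m[1])),
        arm_width_cm=jit(0.048 * h),
        arm_len_cm=jit(0.30 * h),
        arm_angle_deg=float(rng.uniform(20, 30)),
        leg_width_cm=jit(0.072 * h),
        leg_gap_cm=jit(0.04 * h),
        scale_cm_per_px=scale_cm_per_px,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a synthetic study cohort.

    ``betas`` are (b0, b1, b2, b3, b4) of the %BF model documented in the
    module docstring (b1 multiplies BV in liters over height in meters,
    b2 multiplies BMI, b3 the female indicator, b4 the shape-class index).
    """

    n: int = 200
    stratum: str = "adults"  # or "children"
    betas: tuple[float, float, float, float, float] = (-10.0, 0.1, 1.0, 8.0, 3.0)
    noise_sd: float = 3.0
    scale_cm_per_px: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.stratum not in ("adults", "children"):
            raise ValidationError("stratum must be 'adults' or 'children'")


#: Marginal distributions mirroring a mixed community sample: adults
#: (age 38 +- 12 y, height 169 +- 8 cm, BMI 28.7 +- 6.6) and children
#: (age 11 +- 3 y, height 148 +- 15 cm, BMI 20.4 +- 4.4), ~47% female,
#: ~47-61% African American.
_STRATA = {
    "adults": {"age": (38.1, 11.6, 19, 80), "height": (169.2, 8.4, 150, 195),
               "bmi": (28.7, 6.6, 17.0, 46.0), "p_female": 0.465, "p_aa": 0.465},
    "children": {"age": (11.3, 3.3, 6, 18), "height": (148.5, 15.4, 112, 180),
                 "bmi": (20.4, 4.4, 13.5, 33.0), "p_female": 0.474, "p_aa": 0.608},
}

#: Mean soft-tissue density (kg/L) used to map weight to target volume.
BODY_DENSITY_KG_L = 1.04


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(v, lo, hi))


@dataclass(frozen=True)
class SyntheticSubject:
    """One generated subject: covariates, criterion %BF, and image pair."""

    subject_id: str
    age: float
    sex: int  # 1 = female
    race: int  # 1 = African American
    height_cm: float
    weight_kg: float
    bmi: float
    bf_dxa_pct: float
    shape_class: int
    analytic_volume_L: float
    width_scale_capped: bool
    phantom: RenderedPhantom


def _build_phantom(
    height: float, target_volume_L: float, shape_class: int, scale: float, seed: int
) -> tuple[PhantomSpec, bool]:
    """Solve the width multiplier so the phantom hits the target volume.

    Widths of trunk, arms and legs scale together by ``s`` (head and neck
    fixed); since each of those primitive volumes is quadratic in its
    widths, s = sqrt((target - head - neck) / rest). s is capped to a
    plausible anthropometric range and the cap is reported.
    """
    arch = SHAPE_ARCHETYPES[shape_class]
    wb_top, ws_top = 0.225 * height, 0.128 * height
    base = PhantomSpec(
        height_cm=height,
        head_radius_cm=0.064 * height,
        neck_width_cm=0.055 * height,
        neck_len_cm=0.035 * height,
        trunk_len_cm=0.31 * height,
        trunk_back_widths_cm=tuple(wb_top * m for m in arch["back"]),
        trunk_side_widths_cm=tuple(ws_top * m for m in arch["side"]),
        arm_width_cm=0.048 * height,
        arm_len_cm=0.30 * height,
        leg_width_cm=0.072 * height,
        leg_gap_cm=0.04 * height,
        scale_cm_per_px=scale,
        seed=seed,
    )
    parts = base.analytic_volumes_L()
    fixed = parts["head"] + parts["neck"]
    rest = parts["trunk"] + parts["arms"] + parts["legs"]
    s2 = (target_volume_L - fixed) / rest
    s = math.sqrt(max(s2, 0.0))
    capped = not (0.55 <= s <= 1.9)
    s = float(np.clip(s, 0.55, 1.9))
    spec = replace(
        base,
        trunk_back_widths_cm=tuple(w * s for w in base.trunk_back_widths_cm),
        trunk_side_widths_cm=tuple(w * s for w in base.trunk_side_widths_cm),
        arm_width_cm=base.arm_width_cm * s,
        leg_width_cm=base.leg_width_cm * s,
    )
    return spec, capped


def generate_cohort(spec: CohortSpec, out_dir: str | None = None) -> list[SyntheticSubject]:
    """Sample a cohort, realize each subject as a phantom, assign %BF.

    %BF follows the declared generative model with truncation to
    (5, 60). When ``out_dir`` is given, the image pairs are written as
    PNGs alongside a ``cohort.csv`` in the pipeline's input layout.
    """
    if spec.n < 30:
        raise ValidationError("cohort generation requires n >= 30")
    rng = np.random.default_rng(spec.seed)
    dist = _STRATA[spec.stratum]
    b0, b1, b2, b3, b4 = spec.betas
    subjects = []
    for i in range(spec.n):
        age = _trunc_normal(rng, *dist["age"])
        height = _trunc_normal(rng, *dist["height"])
        bmi = _trunc_normal(rng, *dist["bmi"])
        weight = bmi * (height / 100.0) ** 2
        sex = int(rng.random() < dist["p_female"])
        race = int(rng.random() < dist["p_aa"])
        shape_class = int(rng.integers(0, 3))
        target_vol = weight / BODY_DENSITY_KG_L
        ph_spec, capped = _build_phantom(
            height, target_vol, shape_class, spec.scale_cm_per_px,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        phantom = render_phantom(ph_spec)
        bv_true = ph_spec.analytic_volume_L
        bf = (
            b0
            + b1 * bv_true / (height / 100.0)
            + b2 * bmi
            + b3 * sex
            + b4 * shape_class
            + rng.normal(0.0, spec.noise_sd)
        )
        bf = float(np.clip(bf, 5.0 + 1e-6, 60.0 - 1e-6))
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i:04d}",
                age=age, sex=sex, race=race,
                height_cm=height, weight_kg=weight, bmi=bmi,
                bf_dxa_pct=bf, shape_class=shape_class,
                analytic_volume_L=bv_true,
                width_scale_capped=capped,
                phantom=phantom,
            )
        )
    if out_dir is not None:
        _write_cohort(subjects, out_dir)
    return subjects


def _write_cohort(subjects: list[SyntheticSubject], out_dir: str) -> None:
    import os

    import imageio.v3 as iio
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in subjects:
        back_path = os.path.join(out_dir, f"{s.subject_id}_back.png")
        side_path = os.path.join(out_dir, f"{s.subject_id}_side.png")
        iio.imwrite(back_path, s.phantom.back.pixels)
        iio.imwrite(side_path, s.phantom.side.pixels)
        rows.append(
            {
                "subject_id": s.subject_id, "age": s.age, "sex": s.sex, "race": s.race,
                "height_cm": s.height_cm, "weight_kg": s.weight_kg, "bmi": s.bmi,
                "bf_dxa_pct": s.bf_dxa_pct,
                "back_image": os.path.basename(back_path),
                "side_image": os.path.basename(side_path),
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
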