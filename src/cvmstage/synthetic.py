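"""Stage-conditioned synthetic cervical-vertebra annotations and images.

Real CVM datasets are clinical radiographs and rarely shareable, so this
module constructs landmark configurations (and radiograph-like rasters) whose
true stage, concavity depths and BAR ratios are known exactly.  Geometry is
built in millimetres on a canvas mirroring the detector's region-of-interest
scale (100 x 200 px at 0.25 mm/px), then converted to pixels:

* C2 contributes its lower border (corners ``lp``/``la`` and deepest point
  ``m``) under a schematic odontoid body;
* C3 and C4 are quadrilateral bodies whose anterior height and base width
  realise a target BAR, with the lower border drawn as the circular arc
  through ``lp``, ``m``, ``la``;
* R1/R2 reference markers are placed exactly 10 mm apart, so calibration is
  recovered from the record itself.

Depths and BARs are drawn uniformly from the region of measurement space
consistent with the requested stage under the staging thresholds, at a
safety margin from every decision boundary; the generator and the classifier
therefore cannot drift apart.  Landmark jitter (isotropic Gaussian, in mm)
and image noise/blur are controllable and default to the clean setting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import MeasurementSet
from .landmark_io import (
    ANATOMIC_NAMES,
    AnnotationRecord,
    Landmark,
    compute_scale,
    write_labelme,
)
from .staging import CVMStage, StageThresholds

__all__ = [
    "SyntheticParams",
    "SyntheticCase",
    "STAGE_FREQUENCIES",
    "sample_case",
    "jitter_landmarks",
    "render_image",
    "generate_dataset",
]

#: Default per-stage sampling proportions, matching the composition of a
#: typical orthodontic training cohort (young patients over-represent the
#: early stages; CS5 is the rarest).
STAGE_FREQUENCIES: dict[CVMStage, float] = {
    CVMStage.CS1: 242 / 980,
    CVMStage.CS2: 214 / 980,
    CVMStage.CS3: 164 / 980,
    CVMStage.CS4: 108 / 980,
    CVMStage.CS5: 52 / 980,
    CVMStage.CS6: 200 / 980,
}


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration.

    Spatial units are mm except where noted.  ``jitter_sigma_mm`` is the
    isotropic per-landmark annotation noise; ``noise_sigma`` is additive
    Gaussian intensity noise on the rendered image (intensity units, image
    in [0, 1]); ``blur_px`` the Gaussian blur radius in pixels.
    """

    width_px: int = 100
    height_px: int = 200
    mm_per_pixel: float = 0.25
    jitter_sigma_mm: float = 0.0
    noise_sigma: float = 0.03
    blur_px: float = 1.0
    foreground: float = 0.8
    background: float = 0.1
    conc_margin_mm: float = 0.15
    bar_margin: float = 0.05
    # Anterior-height range of the C3/C4 bodies.
    body_height_mm: tuple[float, float] = (8.0, 11.0)

    @property
    def width_mm(self) -> float:
        return self.width_px * self.mm_per_pixel

    @property
    def height_mm(self) -> float:
        return self.height_px * self.mm_per_pixel


@dataclass
class SyntheticCase:
    """A generated annotation with its image and exact ground truth."""

    record: AnnotationRecord
    image: np.ndarray | None
    true_stage: CVMStage
    true_measurements: MeasurementSet


# Concavity flags (C2, C3, C4) per stage; CS4-CS6 differ only in shape.
_STAGE_CONCAVE = {
    CVMStage.CS1: (False, False, False),
    CVMStage.CS2: (True, False, False),
    CVMStage.CS3: (True, True, False),
    CVMStage.CS4: (True, True, True),
    CVMStage.CS5: (True, True, True),
    CVMStage.CS6: (True, True, True),
}


def _conc_range(concave: bool, t: StageThresholds, p: SyntheticParams) -> tuple[float, float]:
    if concave:
        lo = t.concavity_mm + p.conc_margin_mm
        return lo, lo + 1.35
    hi = t.concavity_mm - p.conc_margin_mm
    if hi <= 0:
        raise ValueError("no stage-consistent flat-border region under these thresholds")
    return 0.0, hi


def _bar_range(shape: str, t: StageThresholds, p: SyntheticParams) -> tuple[float, float]:
    if shape == "horizontal":
        lo = t.square_upper_bar + p.bar_margin
        return lo, lo + 0.4
    if shape == "square":
        lo, hi = t.vertical_upper_bar + p.bar_margin, t.square_upper_bar - p.bar_margin
    elif shape == "vertical":
        lo, hi = max(0.45, t.vertical_upper_bar - 0.25), t.vertical_upper_bar - p.bar_margin
    else:  # pragma: no cover
        raise ValueError(shape)
    if hi <= lo:
        raise ValueError(f"empty stage-consistent BAR region for shape {shape!r}")
    return lo, hi


def _stage_shapes(stage: CVMStage, rng: np.random.Generator) -> tuple[str, str]:
    """Draw C3/C4 shape classes compatible with the requested stage."""
    if stage in (CVMStage.CS1, CVMStage.CS2, CVMStage.CS3, CVMStage.CS4):
        return "horizontal", "horizontal"
    if stage is CVMStage.CS5:
        # At least one square, no vertical body.
        options = [("square", "horizontal"), ("horizontal", "square"), ("square", "square")]
    else:  # CS6: at least one vertical body.
        options = [
            ("vertical", "horizontal"), ("horizontal", "vertical"),
            ("vertical", "square"), ("square", "vertical"),
            ("vertical", "vertical"),
        ]
    return options[rng.integers(len(options))]


def sample_case(
    stage: CVMStage,
    rng: np.random.Generator | int | None = None,
    params: SyntheticParams = SyntheticParams(),
    thresholds: StageThresholds = StageThresholds(),
    render: bool = True,
    inconsistent_pattern: bool = False,
    image_id: str = "",
) -> SyntheticCase:
    """Generate one stage-conditioned case with exact ground truth.

    With ``inconsistent_pattern=True`` (CS2/CS3 only) the concave borders
    are placed out of the canonical superior-to-inferior order, for testing
    the ``pattern_consistent`` staging flag.
    """
    rng = np.random.default_rng(rng)
    stage = CVMStage(stage)
    p, t = params, thresholds

    flags = list(_STAGE_CONCAVE[stage])
    if inconsistent_pattern:
        if stage is CVMStage.CS2:
            flags = [False, False, True]
        elif stage is CVMStage.CS3:
            flags = [False, True, True]
        else:
            raise ValueError("inconsistent_pattern applies to CS2/CS3 only")
    concs = [float(rng.uniform(*_conc_range(f, t, p))) for f in flags]
    shapes = _stage_shapes(stage, rng)
    bars = [float(rng.uniform(*_bar_range(s, t, p))) for s in shapes]
    heights = [float(rng.uniform(*p.body_height_mm)) for _ in range(2)]

    W, H = p.width_mm, p.height_mm
    mmpp = p.mm_per_pixel
    x_a = 0.20 * W                      # anterior (left) margin of the bodies
    y_c2, y_c3, y_c4 = 0.32 * H, 0.62 * H, 0.92 * H

    lms: dict[str, tuple[float, float]] = {}
    lms["R1"] = (0.10 * W, 0.05 * H)
    lms["R2"] = (0.10 * W, 0.05 * H + 10.0)

    # C2 lower border: fixed 12 mm chord.
    c2_base = 12.0
    lms["C2la"] = (x_a, y_c2)
    lms["C2lp"] = (x_a + c2_base, y_c2)
    lms["C2m"] = (x_a + c2_base / 2.0, y_c2 - concs[0])

    for name, y_low, h, bar, conc in (
        ("C3", y_c3, heights[0], bars[0], concs[1]),
        ("C4", y_c4, heights[1], bars[1], concs[2]),
    ):
        base = bar * h
        if x_a + base > W - 1.5 * mmpp or y_low - h < 0:
            raise ValueError("synthetic body does not fit the canvas")
        lms[f"{name}la"] = (x_a, y_low)
        lms[f"{name}lp"] = (x_a + base, y_low)
        lms[f"{name}ua"] = (x_a, y_low - h)
        lms[f"{name}up"] = (x_a + base, y_low - h)
        lms[f"{name}m"] = (x_a + base / 2.0, y_low - conc)

    record = AnnotationRecord(
        image_id=image_id,
        image_width=p.width_px,
        image_height=p.height_px,
        gold_stage=stage,
    )
    for name, (xm, ym) in lms.items():
        record.add(Landmark(name, xm / mmpp, ym / mmpp))

    truth = MeasurementSet(
        c2conc=concs[0], c3conc=concs[1], c4conc=concs[2],
        c3bar=bars[0], c4bar=bars[1],
    )
    case = SyntheticCase(
        record=record, image=None, true_stage=stage, true_measurements=truth
    )
    if render:
        case.image = render_image(case, p, rng)
    if p.jitter_sigma_mm > 0:
        case.record = jitter_landmarks(case.record, p.jitter_sigma_mm, rng)
    return case


def jitter_landmarks(
    record: AnnotationRecord, sigma_mm: float, rng: np.random.Generator | int | None = None
) -> AnnotationRecord:
    """Add isotropic Gaussian noise (sigma in mm) to the 13 anatomic points.

    The reference markers R1/R2 are left untouched, so the calibration scale
    is preserved exactly.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(rng)
    scale = compute_scale(record)
    sigma_px = scale.to_px(sigma_mm)
    out = AnnotationRecord(
        image_id=record.image_id,
        image_width=record.image_width,
        image_height=record.image_height,
        gold_stage=record.gold_stage,
        rater_id=record.rater_id,
    )
    for name, lm in record.landmarks.items():
        if name in ANATOMIC_NAMES and sigma_px > 0:
            dx, dy = rng.normal(0.0, sigma_px, size=2)
            out.add(Landmark(name, lm.x + dx, lm.y + dy))
        else:
            out.add(lm)
    return out


def _circle_through(p1, p2, p3):
    """Centre and radius of the circle through three points (None if collinear)."""
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if abs(d) < 1e-12:
        return None
    ux = ((x1**2 + y1**2) * (y2 - y3) + (x2**2 + y2**2) * (y3 - y1)
          + (x3**2 + y3**2) * (y1 - y2)) / d
    uy = ((x1**2 + y1**2) * (x3 - x2) + (x2**2 + y2**2) * (x1 - x3)
          + (x3**2 + y3**2) * (x2 - x1)) / d
    r = math.hypot(x1 - ux, y1 - uy)
    return (ux, uy), r


def _lower_border_path(lp, m, la, n: int = 60) -> np.ndarray:
    """Sampled path lp -> la along the circular arc through m (or the chord)."""
    circ = _circle_through(lp, m, la)
    if circ is None:
        return np.array([lp, la], dtype=float)
    (cx, cy), r = circ
    a0 = math.atan2(lp[1] - cy, lp[0] - cx)
    a1 = math.atan2(la[1] - cy, la[0] - cx)
    am = math.atan2(m[1] - cy, m[0] - cx)
    # Choose the sweep direction that passes through m's angle.
    def sweep(start, end, ccw):
        span = (end - start) % (2 * math.pi)
        if not ccw:
            span = span - 2 * math.pi
        return span
    for ccw in (True, False):
        span = sweep(a0, a1, ccw)
        tm = sweep(a0, am, ccw)
        if span != 0 and 0 <= tm / span <= 1:
            angles = a0 + span * np.linspace(0, 1, n)
            return np.stack([cx + r * np.cos(angles), cy + r * np.sin(angles)], axis=1)
    return np.array([lp, la], dtype=float)  # pragma: no cover


def render_image(
    case: SyntheticCase,
    params: SyntheticParams = SyntheticParams(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Rasterise the vertebral bodies into a noisy grayscale image in [0, 1].

    Bodies are filled polygons at the foreground intensity whose lower
    border follows the circular arc through lp, m, la (the concave notch is
    carved out of the body); reference markers are small bright disks.
    Gaussian blur then additive Gaussian noise are applied per ``params``.
    """
    from skimage.draw import disk, polygon
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(rng)
    p = params
    rec = case.record
    img = np.full((p.height_px, p.width_px), p.background, dtype=float)

    def fill(poly_xy: np.ndarray) -> None:
        rr, cc = polygon(poly_xy[:, 1], poly_xy[:, 0], shape=img.shape)
        img[rr, cc] = p.foreground

    # C2: lower border + schematic body with an odontoid bump.
    la, lp, m = rec.point("C2la"), rec.point("C2lp"), rec.point("C2m")
    mid = (la + lp) / 2.0
    h8 = 8.0 / p.mm_per_pixel
    h12 = 12.0 / p.mm_per_pixel
    body = [
        la + (-1.0, -h8), mid + (-8.0, -h8 * 1.1), mid + (0.0, -h12),
        mid + (8.0, -h8 * 1.1), lp + (1.0, -h8),
    ]
    path = _lower_border_path(tuple(lp), tuple(m), tuple(la))
    fill(np.vstack([np.asarray(body, dtype=float), path]))

    for v in ("C3", "C4"):
        la, lp = rec.point(f"{v}la"), rec.point(f"{v}lp")
        ua, up, m = rec.point(f"{v}ua"), rec.point(f"{v}up"), rec.point(f"{v}m")
        path = _lower_border_path(tuple(lp), tuple(m), tuple(la))
        fill(np.vstack([[ua, up], path]))

    for rname in ("R1", "R2"):
        rr, cc = disk(tuple(rec.point(rname)[::-1]), 2.5, shape=img.shape)
        img[rr, cc] = 1.0

    if p.blur_px > 0:
        img = gaussian_filter(img, p.blur_px)
    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    counts: "dict[CVMStage, int] | list[int] | int",
    seed: int = 0,
    params: SyntheticParams = SyntheticParams(),
    thresholds: StageThresholds = StageThresholds(),
    out_dir: "str | Path | None" = None,
    render: bool = True,
):
    """Generate a seeded dataset; optionally write PNGs, JSONs and a manifest.

    ``counts`` is either a per-stage mapping/list, or a total size to be
    split by :data:`STAGE_FREQUENCIES` (largest-remainder rounding).
    Returns ``(cases, manifest)`` where the manifest is a DataFrame with
    columns ``image_id``, ``true_stage``.
    """
    import pandas as pd

    if isinstance(counts, int):
        total = counts
        raw = {s: STAGE_FREQUENCIES[s] * total for s in CVMStage}
        counts = {s: int(math.floor(v)) for s, v in raw.items()}
        rem = total - sum(counts.values())
        for s in sorted(CVMStage, key=lambda s: raw[s] - math.floor(raw[s]), reverse=True)[:rem]:
            counts[s] += 1
    elif isinstance(counts, (list, tuple)):
        counts = dict(zip(CVMStage, counts))

    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    rows = []
    for s in CVMStage:
        for i in range(int(counts.get(s, 0))):
            image_id = f"{s}_{i:04d}.png"
            case = sample_case(
                s, rng, params=params, thresholds=thresholds,
                render=render, image_id=image_id,
            )
            cases.append(case)
            rows.append({"image_id": image_id, "true_stage": str(s)})
    manifest = pd.DataFrame(rows, columns=["image_id", "true_stage"])

    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for case in cases:
            stem = Path(case.record.image_id).stem
            if case.image is not None:
                arr = (np.clip(case.image, 0, 1) * 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out / f"{stem}.png")
            (out / f"{stem}.json").write_text(write_labelme(case.record))
        manifest.to_csv(out / "manifest.csv", index=False)
    return cases, manifest
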