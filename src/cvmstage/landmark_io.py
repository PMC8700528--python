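"""Landmark annotation I/O, calibration and region-of-interest cropping.

Annotations follow the LabelMe JSON dialect: a top-level ``shapes`` list in
which each labelled point is a shape with ``shape_type == "point"``, a
``label`` and a single ``[x, y]`` coordinate pair.  Fifteen labels form the
working vocabulary: two reference markers ``R1``/``R2`` placed 10 mm apart on
the film's calibration ruler, and thirteen anatomic points on the second,
third and fourth cervical vertebrae (C2-C4) used for morphometric
measurement.

Coordinates are 0-based raster pixels: origin at the image's top-left corner,
x increasing rightward, y increasing downward.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "ANATOMIC_NAMES",
    "REFERENCE_NAMES",
    "Landmark",
    "AnnotationRecord",
    "CalibrationScale",
    "RoiSpec",
    "RoiTransform",
    "AnnotationError",
    "CalibrationError",
    "read_labelme",
    "write_labelme",
    "compute_scale",
    "crop_roi",
]

#: Reference markers on the calibration ruler, 10 mm apart.
REFERENCE_NAMES: tuple[str, ...] = ("R1", "R2")

#: The thirteen anatomic points: lp/la = posterior/anterior corner of the
#: lower border, m = deepest point of the lower-border concavity,
#: up/ua = posterior/anterior corner of the upper border.  C2 (the odontoid
#: vertebra) carries only its lower border.
ANATOMIC_NAMES: tuple[str, ...] = (
    "C2lp", "C2m", "C2la",
    "C3up", "C3ua", "C3lp", "C3m", "C3la",
    "C4up", "C4ua", "C4lp", "C4m", "C4la",
)

#: Full vocabulary in canonical order (also the detector's output order).
LANDMARK_NAMES: tuple[str, ...] = REFERENCE_NAMES + ANATOMIC_NAMES

#: Physical distance between the two reference markers.
REFERENCE_DISTANCE_MM = 10.0


class AnnotationError(ValueError):
    """Invalid or inconsistent landmark annotation."""


class CalibrationError(AnnotationError):
    """Missing or degenerate reference markers."""


@dataclass(frozen=True)
class Landmark:
    """A named point in pixel coordinates (y increases downward)."""

    name: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_NAMES:
            raise AnnotationError(f"unknown landmark name {self.name!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise AnnotationError(f"non-finite coordinates for {self.name}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class AnnotationRecord:
    """One image's named landmarks plus optional gold stage and rater id."""

    image_id: str = ""
    landmarks: dict[str, Landmark] = field(default_factory=dict)
    image_width: int | None = None
    image_height: int | None = None
    gold_stage: "object | None" = None  # CVMStage; kept loose to avoid cycle
    rater_id: str | None = None

    def add(self, lm: Landmark) -> None:
        if lm.name in self.landmarks:
            raise AnnotationError(f"duplicate landmark label {lm.name!r}")
        self.landmarks[lm.name] = lm

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks

    def __getitem__(self, name: str) -> Landmark:
        try:
            return self.landmarks[name]
        except KeyError:
            raise AnnotationError(
                f"record {self.image_id!r} is missing landmark {name!r}"
            ) from None

    def point(self, name: str) -> np.ndarray:
        return self[name].xy

    @property
    def is_stageable(self) -> bool:
        """True iff R1, R2 and all 13 anatomic points are present."""
        return all(n in self.landmarks for n in LANDMARK_NAMES)

    def missing(self) -> list[str]:
        return [n for n in LANDMARK_NAMES if n not in self.landmarks]

    def require_stageable(self) -> None:
        miss = self.missing()
        if miss:
            raise AnnotationError(
                f"record {self.image_id!r} is not stageable; "
                f"missing landmarks: {', '.join(miss)}"
            )


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-millimetre conversion factor for one image."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_pixel) and self.mm_per_pixel > 0):
            raise CalibrationError(
                f"mm_per_pixel must be positive and finite, "
                f"got {self.mm_per_pixel}"
            )

    def to_mm(self, pixels: float) -> float:
        return pixels * self.mm_per_pixel

    def to_px(self, mm: float) -> float:
        return mm / self.mm_per_pixel


@dataclass(frozen=True)
class RoiSpec:
    """Output geometry of the C2-C4 region-of-interest crop."""

    width: int = 100
    height: int = 200
    margin_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.margin_fraction < 0:
            raise ValueError("margin_fraction must be non-negative")


@dataclass(frozen=True)
class RoiTransform:
    """Affine map full-image -> ROI: roi = (full - offset) * scale."""

    offset_x: float
    offset_y: float
    scale_x: float
    scale_y: float

    def forward(self, x: float, y: float) -> tuple[float, float]:
        return (x - self.offset_x) * self.scale_x, (y - self.offset_y) * self.scale_y

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        return x / self.scale_x + self.offset_x, y / self.scale_y + self.offset_y


def read_labelme(json_text: str) -> AnnotationRecord:
    """Parse a LabelMe JSON document into an :class:`AnnotationRecord`.

    Point shapes with recognised labels become landmarks.  Unknown labels and
    non-point shapes are reported with a warning, never silently dropped.
    Duplicate landmark labels raise :class:`AnnotationError`.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed LabelMe JSON: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("shapes", []), list):
        raise AnnotationError("LabelMe document must contain a 'shapes' list")

    flags = doc.get("flags") or {}
    gold_stage = None
    if isinstance(flags, dict) and flags.get("gold_stage"):
        from .staging import CVMStage

        gold_stage = CVMStage(flags["gold_stage"])

    rec = AnnotationRecord(
        image_id=str(doc.get("imagePath", "") or ""),
        image_width=doc.get("imageWidth"),
        image_height=doc.get("imageHeight"),
        gold_stage=gold_stage,
        rater_id=flags.get("rater_id") if isinstance(flags, dict) else None,
    )
    for shape in doc.get("shapes", []):
        label = shape.get("label")
        stype = shape.get("shape_type", "point")
        if stype != "point":
            warnings.warn(
                f"ignoring non-point shape {label!r} (shape_type={stype!r})",
                stacklevel=2,
            )
            continue
        if label not in LANDMARK_NAMES:
            warnings.warn(f"ignoring unknown landmark label {label!r}", stacklevel=2)
            continue
        points = shape.get("points") or []
        if len(points) != 1 or len(points[0]) != 2:
            raise AnnotationError(
                f"point shape {label!r} must have exactly one [x, y] pair"
            )
        x, y = points[0]
        rec.add(Landmark(label, float(x), float(y)))
    return rec


def write_labelme(record: AnnotationRecord, indent: int | None = 2) -> str:
    """Serialize a record to LabelMe JSON; inverse of :func:`read_labelme`."""
    flags: dict[str, object] = {}
    if record.gold_stage is not None:
        flags["gold_stage"] = str(record.gold_stage)
    if record.rater_id is not None:
        flags["rater_id"] = record.rater_id
    doc = {
        "version": "5.0.0",
        "flags": flags,
        "shapes": [
            {
                "label": lm.name,
                "points": [[lm.x, lm.y]],
                "group_id": None,
                "shape_type": "point",
                "flags": {},
            }
            for name, lm in sorted(
                record.landmarks.items(), key=lambda kv: LANDMARK_NAMES.index(kv[0])
            )
        ],
        "imagePath": record.image_id,
        "imageHeight": record.image_height,
        "imageWidth": record.image_width,
    }
    return json.dumps(doc, indent=indent)


def compute_scale(record: AnnotationRecord) -> CalibrationScale:
    """Derive mm/pixel from the 10 mm R1-R2 reference distance."""
    for name in REFERENCE_NAMES:
        if name not in record:
            raise CalibrationError(
                f"record {record.image_id!r} lacks reference marker {name}"
            )
    d = float(np.hypot(*(record.point("R1") - record.point("R2"))))
    if d <= 0.0:
        raise CalibrationError("reference markers R1 and R2 coincide")
    return CalibrationScale(REFERENCE_DISTANCE_MM / d)


def crop_roi(
    image: np.ndarray,
    record: AnnotationRecord,
    spec: RoiSpec = RoiSpec(),
) -> tuple[np.ndarray, AnnotationRecord, RoiTransform]:
    """Crop the C2-C4 region and re-express landmarks in ROI coordinates.

    The crop window is the bounding box of the 13 anatomic points expanded on
    each side by ``margin_fraction`` of the box size, then resampled to
    ``spec.width`` x ``spec.height``.  Returns the ROI raster, a transformed
    record (all landmarks, including R1/R2, mapped into ROI pixels) and the
    affine :class:`RoiTransform` for exact mapping back to the full image.
    """
    record.require_stageable()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    h, w = img.shape
    pts = np.array([record.point(n) for n in ANATOMIC_NAMES])
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > w - 1 or pts[:, 1].max() > h - 1):
        raise AnnotationError("anatomic landmarks fall outside the image bounds")

    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    bw, bh = x1 - x0, y1 - y0
    x0 -= spec.margin_fraction * bw
    x1 += spec.margin_fraction * bw
    y0 -= spec.margin_fraction * bh
    y1 += spec.margin_fraction * bh
    if x1 <= x0 or y1 <= y0:
        raise AnnotationError("degenerate landmark bounding box")

    tr = RoiTransform(
        offset_x=x0, offset_y=y0,
        scale_x=(spec.width - 1) / (x1 - x0),
        scale_y=(spec.height - 1) / (y1 - y0),
    )

    # Bilinear resampling of the window onto the target grid.
    xs = np.linspace(x0, x1, spec.width)
    ys = np.linspace(y0, y1, spec.height)
    gx, gy = np.meshgrid(np.clip(xs, 0, w - 1), np.clip(ys, 0, h - 1))
    ix0 = np.clip(np.floor(gx).astype(int), 0, w - 2)
    iy0 = np.clip(np.floor(gy).astype(int), 0, h - 2)
    fx, fy = gx - ix0, gy - iy0
    roi = (
        img[iy0, ix0] * (1 - fx) * (1 - fy)
        + img[iy0, ix0 + 1] * fx * (1 - fy)
        + img[iy0 + 1, ix0] * (1 - fx) * fy
        + img[iy0 + 1, ix0 + 1] * fx * fy
    )

    out = AnnotationRecord(
        image_id=record.image_id,
        image_width=spec.width,
        image_height=spec.height,
        gold_stage=record.gold_stage,
        rater_id=record.rater_id,
    )
    for name, lm in record.landmarks.items():
        rx, ry = tr.forward(lm.x, lm.y)
        out.add(Landmark(name, rx, ry))
    return roi, out, tr
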