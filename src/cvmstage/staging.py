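"""Rule-based CVM staging (CS1-CS6) from the five morphometric measurements.

The Baccetti-style decision workflow reads two kinds of evidence:

1. How many lower borders (C2, C3, C4) carry a visible concavity.  Zero
   concave borders -> CS1, one -> CS2, two -> CS3.
2. Once all three borders are concave (CS4-CS6), the C3/C4 body shape
   decides the tier: horizontal rectangle -> CS4, at least one square ->
   CS5, at least one vertical rectangle -> CS6 (the most mature shape wins).

The numeric thresholds are configurable: the conventional 1.0 mm visibility
criterion for a concavity, and BAR bands (vertical <= 0.95 < square <= 1.2 <
horizontal) for the shape classes.  Boundary ties are counted on the mature
side.  Staging uses the *number* of concave borders rather than their
identity, so noisy annotations with anatomically out-of-order patterns (e.g.
C4 concave while C2 flat) still receive a stage, flagged
``pattern_consistent=False``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .geometry import MeasurementSet, measure
from .landmark_io import AnnotationRecord, compute_scale

__all__ = [
    "CVMStage",
    "ShapeClass",
    "StageThresholds",
    "StagingResult",
    "detect_concavity",
    "classify_shape",
    "stage",
    "stage_record",
]


class CVMStage(str, enum.Enum):
    """The six cervical-vertebral-maturation stages, ordered CS1 < ... < CS6."""

    CS1 = "CS1"
    CS2 = "CS2"
    CS3 = "CS3"
    CS4 = "CS4"
    CS5 = "CS5"
    CS6 = "CS6"

    @property
    def index(self) -> int:
        """1-based numeric code (CS1 -> 1 ... CS6 -> 6)."""
        return int(self.value[2])

    def __lt__(self, other: "CVMStage") -> bool:  # type: ignore[override]
        return self.index < other.index

    def __le__(self, other: "CVMStage") -> bool:  # type: ignore[override]
        return self.index <= other.index

    def __gt__(self, other: "CVMStage") -> bool:  # type: ignore[override]
        return self.index > other.index

    def __ge__(self, other: "CVMStage") -> bool:  # type: ignore[override]
        return self.index >= other.index

    def __str__(self) -> str:
        return self.value


class ShapeClass(str, enum.Enum):
    """Vertebral-body shape from the BAR value.

    ``horizontal`` covers both the immature trapezoid and the horizontal
    rectangle: with only the base/anterior-height ratio available the two
    are indistinguishable, and the early/late split is carried entirely by
    the concavity counts.
    """

    HORIZONTAL = "horizontal"
    SQUARE = "square"
    VERTICAL = "vertical"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class StageThresholds:
    """Decision thresholds; defaults are engineering choices, all overridable.

    concavity_mm
        Minimum concavity depth counted as a visible concavity (mm).
    square_upper_bar
        BAR at or below which (and above ``vertical_upper_bar``) a body is
        square.
    vertical_upper_bar
        BAR at or below which a body is a vertical rectangle.
    """

    concavity_mm: float = 1.0
    square_upper_bar: float = 1.2
    vertical_upper_bar: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.vertical_upper_bar < self.square_upper_bar):
            raise ValueError(
                "require 0 < vertical_upper_bar < square_upper_bar"
            )
        if self.concavity_mm <= 0:
            raise ValueError("concavity_mm must be positive")


@dataclass(frozen=True)
class StagingResult:
    """Assigned stage plus the intermediate decisions that produced it."""

    stage: CVMStage
    concave_c2: bool
    concave_c3: bool
    concave_c4: bool
    c3_shape: ShapeClass
    c4_shape: ShapeClass
    pattern_consistent: bool

    def as_dict(self) -> dict[str, object]:
        return {
            "stage": str(self.stage),
            "concave_c2": self.concave_c2,
            "concave_c3": self.concave_c3,
            "concave_c4": self.concave_c4,
            "c3_shape": str(self.c3_shape),
            "c4_shape": str(self.c4_shape),
            "pattern_consistent": self.pattern_consistent,
        }


def detect_concavity(conc_mm: float, thresholds: StageThresholds = StageThresholds()) -> bool:
    """True iff the depth reaches the visibility threshold (tie counts)."""
    if conc_mm < 0:
        raise ValueError("concavity depth must be non-negative")
    return conc_mm >= thresholds.concavity_mm


def classify_shape(bar: float, thresholds: StageThresholds = StageThresholds()) -> ShapeClass:
    """Map a BAR value to its shape class (ties on the mature side)."""
    if bar <= 0:
        raise ValueError("BAR must be positive")
    if bar <= thresholds.vertical_upper_bar:
        return ShapeClass.VERTICAL
    if bar <= thresholds.square_upper_bar:
        return ShapeClass.SQUARE
    return ShapeClass.HORIZONTAL


# Concavity patterns following the canonical superior-to-inferior order of
# maturation (C2 first, then C3, then C4).
_CANONICAL_PATTERNS = frozenset(
    [
        (False, False, False),
        (True, False, False),
        (True, True, False),
        (True, True, True),
    ]
)


def stage(
    measurements: MeasurementSet,
    thresholds: StageThresholds = StageThresholds(),
) -> StagingResult:
    """Assign a CVM stage from a measurement set.

    The number of concave borders fixes CS1-CS3 (0, 1, 2) and routes three
    concave borders into the shape tier, where the most mature C3/C4 shape
    decides: any vertical body -> CS6, else any square -> CS5, else CS4.
    """
    flags = (
        detect_concavity(measurements.c2conc, thresholds),
        detect_concavity(measurements.c3conc, thresholds),
        detect_concavity(measurements.c4conc, thresholds),
    )
    c3_shape = classify_shape(measurements.c3bar, thresholds)
    c4_shape = classify_shape(measurements.c4bar, thresholds)
    k = sum(flags)
    if k == 0:
        result = CVMStage.CS1
    elif k == 1:
        result = CVMStage.CS2
    elif k == 2:
        result = CVMStage.CS3
    else:
        shapes = {c3_shape, c4_shape}
        if ShapeClass.VERTICAL in shapes:
            result = CVMStage.CS6
        elif ShapeClass.SQUARE in shapes:
            result = CVMStage.CS5
        else:
            result = CVMStage.CS4
    return StagingResult(
        stage=result,
        concave_c2=flags[0],
        concave_c3=flags[1],
        concave_c4=flags[2],
        c3_shape=c3_shape,
        c4_shape=c4_shape,
        pattern_consistent=flags in _CANONICAL_PATTERNS,
    )


def stage_record(
    record: AnnotationRecord,
    thresholds: StageThresholds = StageThresholds(),
) -> StagingResult:
    """Calibrate, measure and stage a full 15-landmark record."""
    record.require_stageable()
    scale = compute_scale(record)
    return stage(measure(record, scale), thresholds)
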