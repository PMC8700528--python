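"""Morphometric measurements of the cervical vertebral bodies.

Five scalars summarise C2-C4 morphology:

* ``C2Conc``, ``C3Conc``, ``C4Conc`` — depth (mm) of the lower-border
  concavity: the perpendicular distance from the deepest point ``m`` to the
  chord joining the lower-border corners ``lp``-``la``.  A flat or convex
  border has depth 0 (signed distances on the convex side are clamped).
* ``C3BAR``, ``C4BAR`` — base-to-anterior-height ratio of the vertebral
  body: |lp - la| / |ua - la|.  Dimensionless, so pixel calibration cancels.

With maturation the concavities deepen and BAR falls as the bodies elongate
vertically, which is what the staging rules read off these numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import AnnotationRecord, CalibrationScale, compute_scale

__all__ = [
    "MeasurementSet",
    "GeometryError",
    "point_line_distance",
    "concavity",
    "bar_ratio",
    "measure",
]

#: Anterior heights below this many pixels are treated as degenerate.
_MIN_HEIGHT_PX = 0.5


class GeometryError(ValueError):
    """Degenerate geometry (coincident chord points, zero height...)."""


@dataclass(frozen=True)
class MeasurementSet:
    """The five morphometric quantities for one image."""

    c2conc: float  # mm
    c3conc: float  # mm
    c4conc: float  # mm
    c3bar: float   # dimensionless
    c4bar: float   # dimensionless

    def as_dict(self) -> dict[str, float]:
        return {
            "c2conc_mm": self.c2conc,
            "c3conc_mm": self.c3conc,
            "c4conc_mm": self.c4conc,
            "c3bar": self.c3bar,
            "c4bar": self.c4bar,
        }


def point_line_distance(p, a, b) -> float:
    """Signed perpendicular distance (pixels) from ``p`` to line ``a``-``b``.

    In the raster frame (y down) the sign is positive when ``p`` lies on the
    side of the directed line a->b toward decreasing y for a left-to-right
    chord — i.e. superiorly, the direction of a true lower-border concavity.
    Magnitude is |cross(b-a, p-a)| / |b-a|.
    """
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    norm = float(np.hypot(*ab))
    if norm == 0.0:
        raise GeometryError("degenerate line: a == b")
    cross = ab[0] * (p - a)[1] - ab[1] * (p - a)[0]
    return -float(cross) / norm


def _orient_sign(lp, la, superior_ref) -> float:
    """+1 if the raw signed distance of ``superior_ref`` is positive."""
    d = point_line_distance(superior_ref, lp, la)
    return 1.0 if d >= 0 else -1.0


def concavity(lp, la, m, scale: CalibrationScale, superior_ref=None) -> float:
    """Concavity depth in mm: clamped signed distance of ``m`` to lp-la.

    ``superior_ref`` is any point known to lie on the superior side of the
    chord (e.g. the vertebra's upper-border landmarks); it anchors the sign
    so the depth is invariant under global rotation of the annotation.  When
    omitted, the raster convention (superior = decreasing y) is used.
    """
    d = point_line_distance(m, lp, la)
    if superior_ref is not None:
        d *= _orient_sign(lp, la, superior_ref)
    return scale.to_mm(max(0.0, d))


def bar_ratio(lp, la, ua) -> float:
    """Base-to-anterior-height ratio |lp - la| / |ua - la|."""
    lp, la, ua = (np.asarray(v, dtype=float) for v in (lp, la, ua))
    height = float(np.hypot(*(ua - la)))
    if height < _MIN_HEIGHT_PX:
        raise GeometryError(
            f"degenerate anterior height {height:.3g} px (< {_MIN_HEIGHT_PX})"
        )
    return float(np.hypot(*(lp - la))) / height


def measure(
    record: AnnotationRecord, scale: CalibrationScale | None = None
) -> MeasurementSet:
    """Compute all five measurements from a stageable record.

    The concavity sign for C3/C4 is anchored on each body's own upper-border
    midpoint; for C2 (which has no upper-border landmarks) on the side of
    the C2 chord opposite the C3 body, since C3 lies inferior to C2.
    """
    record.require_stageable()
    if scale is None:
        scale = compute_scale(record)
    pt = record.point

    c3_upper_mid = (pt("C3up") + pt("C3ua")) / 2.0
    c4_upper_mid = (pt("C4up") + pt("C4ua")) / 2.0
    # Superior side of the C2 chord: away from the C3 body.
    c2_sign = -_orient_sign(pt("C2lp"), pt("C2la"), c3_upper_mid)

    d2 = point_line_distance(pt("C2m"), pt("C2lp"), pt("C2la")) * c2_sign
    return MeasurementSet(
        c2conc=scale.to_mm(max(0.0, d2)),
        c3conc=concavity(pt("C3lp"), pt("C3la"), pt("C3m"), scale, c3_upper_mid),
        c4conc=concavity(pt("C4lp"), pt("C4la"), pt("C4m"), scale, c4_upper_mid),
        c3bar=bar_ratio(pt("C3lp"), pt("C3la"), pt("C3ua")),
        c4bar=bar_ratio(pt("C4lp"), pt("C4la"), pt("C4ua")),
    )
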