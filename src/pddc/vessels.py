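"""Vertebrobasilar artery morphometry.

Measurements follow the clinical convention for TOF-MRA readings:

* **Vertebral diameter** — starting at the vertebrobasilar confluence, the
  vessel width is sampled at three points 0.3 cm apart along each vertebral
  artery and averaged.
* **Dominance** — a side is dominant when the bilateral diameter difference
  is >= 0.3 mm; the asymmetry is additionally graded as
  Grade I (0.04-0.70 mm), Grade II (0.71-1.17 mm), Grade III (1.18-2.67 mm).
  Band edges use half-open midpoint boundaries (0.705, 1.175) so the grades
  partition [0.04, 2.67] without gaps.  Grading and dominance are decoupled:
  differences in [0.04, 0.3) are graded but not dominant.
* **Basilar curvature** — BAL is the straight chord between the basilar
  endpoints; BL is the maximum perpendicular distance from the centerline to
  that chord; the curvature type (normal / C / reverse-C / S) is read from
  the signed lateral deviation profile, with positive deviation toward the
  subject's left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Centerline",
    "VertebralPair",
    "DominanceResult",
    "BasilarShape",
    "measure_diameter",
    "assess_dominance",
    "grade_difference",
    "basilar_metrics",
    "morphometry_row",
]

DOMINANCE_THRESHOLD_MM = 0.3
GRADE_BANDS = ((0.04, 0.705, "I"), (0.705, 1.175, "II"), (1.175, 2.67, "III"))
CURVATURE_THRESHOLD_MM = 2.0
MEASUREMENT_SPACING_MM = 3.0  # three points separated by 0.3 cm


@dataclass
class Centerline:
    """Ordered mm coordinates along a vessel axis with cumulative arc length."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 3:
            raise ValueError("centerline needs >= 3 points of 3D mm coordinates")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("duplicate consecutive centerline points")
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of the position at arc length ``s``."""
        s = float(np.clip(s, 0.0, self.total_length))
        return np.array(
            [np.interp(s, self.arc_length, self.points[:, i]) for i in range(3)]
        )


@dataclass
class VertebralPair:
    left_diameter: float
    right_diameter: float
    measurement_points: tuple = ()

    def __post_init__(self) -> None:
        if self.left_diameter <= 0 or self.right_diameter <= 0:
            raise ValueError("diameters must be positive")


@dataclass
class DominanceResult:
    dominant_side: str  # left | right | none
    diff_mm: float
    grade: str  # I | II | III | ungraded


@dataclass
class BasilarShape:
    bal_mm: float  # endpoint chord length
    bl_mm: float  # bending length: max perpendicular deviation from the chord
    curvature_type: str  # normal | C | reverse_C | S


def measure_diameter(
    centerline: Centerline,
    width_field,
    start_at_confluence: float = 0.0,
    from_end: bool = False,
) -> tuple[float, tuple[float, float, float]]:
    """Three-point averaged vessel diameter.

    Width is sampled at arc positions 0, 3 and 6 mm from the starting point
    (the confluence); ``from_end=True`` measures backwards from the far end
    of the centerline, for vertebral lines ordered toward the confluence.
    Returns the mean diameter and the three sampled arc positions.
    """
    offsets = np.array([0.0, MEASUREMENT_SPACING_MM, 2 * MEASUREMENT_SPACING_MM])
    if from_end:
        positions = centerline.total_length - start_at_confluence - offsets
    else:
        positions = start_at_confluence + offsets
    if positions.min() < -1e-9 or positions.max() > centerline.total_length + 1e-9:
        raise ValueError(
            "centerline too short: need 0.6 cm of arc beyond the starting point"
        )
    widths = np.asarray(width_field(positions), dtype=float)
    return float(widths.mean()), tuple(float(p) for p in positions)


def grade_difference(diff_mm: float) -> str:
    for lo, hi, grade in GRADE_BANDS:
        last = grade == "III"
        if lo <= diff_mm < hi or (last and lo <= diff_mm <= hi):
            return grade
    return "ungraded"


def assess_dominance(pair: VertebralPair) -> DominanceResult:
    """Dominance decision (>= 0.3 mm) plus asymmetry grading."""
    diff = abs(pair.left_diameter - pair.right_diameter)
    if diff >= DOMINANCE_THRESHOLD_MM:
        side = "left" if pair.left_diameter > pair.right_diameter else "right"
    else:
        side = "none"
    return DominanceResult(side, float(diff), grade_difference(diff))


def _signed_deviation(points: np.ndarray) -> np.ndarray:
    """Signed perpendicular deviation of each point from the endpoint chord.

    The sign is taken along the component of the volume's left-right (+x)
    axis orthogonal to the chord (radiological laterality convention).
    """
    a, b = points[0], points[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm < 1e-9:
        raise ValueError("degenerate centerline: endpoints coincide")
    u = chord / norm
    rel = points - a
    perp = rel - np.outer(rel @ u, u)
    lateral = np.array([1.0, 0.0, 0.0])
    lateral = lateral - (lateral @ u) * u
    if np.linalg.norm(lateral) < 1e-12:
        # chord along x: fall back to +y for the sign reference
        lateral = np.array([0.0, 1.0, 0.0])
        lateral = lateral - (lateral @ u) * u
    lateral /= np.linalg.norm(lateral)
    signed = perp @ lateral
    mags = np.linalg.norm(perp, axis=1)
    return np.where(np.abs(signed) > 1e-12, np.sign(signed) * mags, 0.0)


def basilar_metrics(
    centerline: Centerline, curvature_threshold_mm: float = CURVATURE_THRESHOLD_MM
) -> BasilarShape:
    """Chord length (BAL), bending length (BL) and curvature type.

    Type rules on the signed deviation profile: no excursion beyond the
    threshold -> normal; excursions on one side only -> C (left) or
    reverse-C (right); above-threshold excursions on both sides -> S.
    """
    dev = _signed_deviation(centerline.points)
    a, b = centerline.points[0], centerline.points[-1]
    bal = float(np.linalg.norm(b - a))
    bl = float(np.max(np.abs(dev)))
    pos = float(dev.max())
    neg = float(-dev.min())
    thr = curvature_threshold_mm
    if pos >= thr and neg >= thr:
        ctype = "S"
    elif pos >= thr:
        ctype = "C"
    elif neg >= thr:
        ctype = "reverse_C"
    else:
        ctype = "normal"
    return BasilarShape(bal, bl, ctype)


def morphometry_row(
    subject_id: str,
    left_mm: float,
    right_mm: float,
    basilar: BasilarShape,
) -> dict:
    """One CSV-ready results row for the cohort morphometry table."""
    dom = assess_dominance(VertebralPair(left_mm, right_mm))
    return {
        "subject": subject_id,
        "left_mm": left_mm,
        "right_mm": right_mm,
        "diff_mm": dom.diff_mm,
        "dominant_side": dom.dominant_side,
        "grade": dom.grade,
        "bal_mm": basilar.bal_mm,
        "bl_mm": basilar.bl_mm,
        "curvature_type": basilar.curvature_type,
    }
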