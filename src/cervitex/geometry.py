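"""Vertebral-curve geometry: end-tangent angles and chord-enclosed area.

A smooth curve is interpolated through the ordered C1...C7 vertebral
landmarks of a lateral cervical radiograph.  Three scalars summarise the
neck posture: the angle between the global horizontal and the curve
tangent at C7 (``angle_1``), the same at C1 (``angle_2``), and the area
enclosed between the curve and the straight C1-C7 chord.

Landmarks live in image coordinates (origin top-left, x rightward, y
downward); angles are reported in [0, 180) degrees as they would be read
on an upright radiograph, i.e. against the horizontal with y flipped up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class LandmarkSet:
    """Ordered head-to-base landmark chain (C1 first, C7 last)."""

    points: np.ndarray          # (n, 2) array of [x, y] pixel coordinates
    pixel_size: float = 0.175   # mm per pixel

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("landmarks must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("at least 3 landmarks required")
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(d == 0):
            raise ValueError("landmarks must be pairwise distinct")


class VertebralCurve:
    """Chord-length parameterised interpolating cubic spline through landmarks.

    The spline (not-a-knot end conditions) passes through every landmark
    and is queried for dense samples and end tangents.  ``samples_per_segment``
    controls the sampling density used for the area integral.
    """

    def __init__(self, landmarks: LandmarkSet, samples_per_segment: int = 200):
        self.landmarks = landmarks
        pts = landmarks.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        self._t = t / t[-1]
        self._sx = CubicSpline(self._t, pts[:, 0])
        self._sy = CubicSpline(self._t, pts[:, 1])
        self.samples_per_segment = samples_per_segment

    def sample(self, n: int | None = None) -> np.ndarray:
        """Return an (n, 2) dense polyline along the curve, C1 to C7."""
        if n is None:
            n = self.samples_per_segment * (len(self.landmarks.points) - 1) + 1
        t = np.union1d(np.linspace(0.0, 1.0, n), self._t)  # knots always hit
        return np.column_stack([self._sx(t), self._sy(t)])

    def tangent(self, t: float) -> np.ndarray:
        v = np.array([self._sx(t, 1), self._sy(t, 1)], dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("degenerate (zero-length) tangent")
        return v / norm


@dataclass
class GeometryFeatures:
    angle_1: float        # degrees, tangent at C7 vs horizontal
    angle_2: float        # degrees, tangent at C1 vs horizontal
    area_px2: float       # enclosed area in pixel^2
    area_mm2: float       # enclosed area calibrated by pixel_size^2
    self_intersecting: bool = False


def fit_curve(landmarks: LandmarkSet, samples_per_segment: int = 200) -> VertebralCurve:
    """Interpolate a smooth curve through >= 3 ordered distinct landmarks."""
    return VertebralCurve(landmarks, samples_per_segment)


def end_tangent_angle(curve: VertebralCurve, end: str) -> float:
    """Angle in [0, 180) between the horizontal and the curve tangent at an end.

    ``end`` is ``"C1"`` (first landmark, head end) or ``"C7"`` (last
    landmark, base end).  Image y points downward, so the vertical
    component is negated to report the angle in upright orientation.
    """
    if end not in ("C1", "C7"):
        raise ValueError("end must be 'C1' or 'C7'")
    v = curve.tangent(0.0 if end == "C1" else 1.0)
    ang = np.degrees(np.arctan2(-v[1], v[0])) % 180.0
    return float(ang)


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _closed_polygon_self_intersects(poly: np.ndarray) -> bool:
    # cheap necessary check: a simple closed curve crosses its chord at
    # most at the endpoints; flag sign changes of the chord-side signed
    # distance in the interior.
    a, b = poly[0], poly[-1]
    d = b - a
    rel = poly[1:-1] - a
    side = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    s = np.sign(side[np.abs(side) > 1e-9])
    return bool(len(s) and np.any(s[:-1] != s[1:]))


def enclosed_area(curve: VertebralCurve) -> tuple[float, float, bool]:
    """Area between the curve and the straight C1-C7 chord.

    Returns ``(area_px2, area_mm2, self_intersecting)``.  The sampled
    curve closed by the chord forms a polygon whose absolute shoelace
    area is reported; if the region crosses the chord the absolute value
    is still returned, with a warning flag.
    """
    poly = curve.sample()
    if np.allclose(poly[0], poly[-1]):
        raise ValueError("curve endpoints coincide; chord is degenerate")
    area = _shoelace(poly)
    px = curve.landmarks.pixel_size
    return float(area), float(area * px * px), _closed_polygon_self_intersects(poly)


def geometry_features(landmarks: LandmarkSet) -> GeometryFeatures:
    """Bundle angle_1, angle_2 and the enclosed area for one landmark set."""
    curve = fit_curve(landmarks)
    a_px, a_mm, warn = enclosed_area(curve)
    return GeometryFeatures(
        angle_1=end_tangent_angle(curve, "C7"),
        angle_2=end_tangent_angle(curve, "C1"),
        area_px2=a_px,
        area_mm2=a_mm,
        self_intersecting=warn,
    )
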