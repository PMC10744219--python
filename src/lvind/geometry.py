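"""Contour geometry: LV axis, centre of contraction, and per-point inward displacement.

Inward displacement (InD) of an endocardial point is the component of its
ED->ES displacement vector directed toward the LV centre of contraction.
The centre sits on the base-to-apex axis at a fraction of the axis length
that slides from one half (basal points) to two thirds (apical points).
InD is measured in mm and normalised to the ED point-to-centre distance,
so 100 % is the theoretical limit at which the cavity shrinks onto the
centreline: inward motion is positive, akinesis is 0 %, outward
(dyskinetic) motion is negative.

The axis and the centres are computed from the ED contour only and held
fixed for ES, so the target of the motion is defined in the ED frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import LaxContour, MIN_CONTOUR_POINTS

_EPS = 1e-9


@dataclass(frozen=True)
class LvAxis:
    """Base-midpoint -> apex reference line of the LV cavity."""

    base_mid: np.ndarray
    apex: np.ndarray
    length_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_mid", np.asarray(self.base_mid, dtype=float))
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        if self.length_mm <= 0:
            raise ValueError("axis length must be positive")
        if abs(np.linalg.norm(self.apex - self.base_mid) - self.length_mm) > 1e-6:
            raise ValueError("length_mm inconsistent with base_mid/apex")

    @property
    def unit(self) -> np.ndarray:
        """Unit vector pointing from base midpoint to apex."""
        return (self.apex - self.base_mid) / self.length_mm


@dataclass(frozen=True)
class CenterRule:
    """Where the centre of contraction sits along the axis.

    ``f_base`` and ``f_apex`` are the axis-length fractions used for the
    most basal and most apical points (defaults 1/2 and 2/3). ``continuous``
    mode interpolates linearly in the point's longitudinal fraction;
    ``discrete3`` uses three levels (basal / mid / apical thirds).
    """

    f_base: float = 0.5
    f_apex: float = 2.0 / 3.0
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if not (0.0 < self.f_base <= self.f_apex < 1.0):
            raise ValueError("require 0 < f_base <= f_apex < 1")
        if self.mode not in ("continuous", "discrete3"):
            raise ValueError(f"unknown center rule mode {self.mode!r}")


@dataclass(frozen=True)
class PointInD:
    """One tracked endocardial point with its inward displacement."""

    p_ed: np.ndarray
    p_es: np.ndarray
    center: np.ndarray
    longitudinal_fraction: float
    ind_mm: float
    ind_pct: float


def fit_axis(contour_ed: LaxContour) -> LvAxis:
    """Fit the LV axis from an ED contour.

    The base midpoint is the midpoint of the two annulus insertions (first
    and last contour points); the apex is the contour point farthest from
    it, which is correct for any convex cavity shape.
    """
    pts = contour_ed.points
    base_mid = 0.5 * (pts[0] + pts[-1])
    dist = np.linalg.norm(pts - base_mid, axis=1)
    i = int(np.argmax(dist))
    length = float(dist[i])
    if length <= _EPS:
        raise ValueError("zero-length axis")
    return LvAxis(base_mid=base_mid, apex=pts[i], length_mm=length)


def longitudinal_fraction(p: np.ndarray, axis: LvAxis) -> float:
    """Normalised base->apex position of a point, clamped to [0, 1].

    Clamping absorbs annulus points that project marginally outside the
    axis because of contouring noise.
    """
    f = float(np.dot(np.asarray(p, dtype=float) - axis.base_mid, axis.unit) / axis.length_mm)
    return min(max(f, 0.0), 1.0)


def contraction_center(f: float, axis: LvAxis, rule: CenterRule = CenterRule()) -> np.ndarray:
    """Centre of contraction for a point at longitudinal fraction ``f``."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("longitudinal fraction must be in [0, 1]")
    if rule.mode == "continuous":
        g = rule.f_base + f * (rule.f_apex - rule.f_base)
    else:  # discrete3
        if f < 1.0 / 3.0:
            g = rule.f_base
        elif f < 2.0 / 3.0:
            g = 0.5 * (rule.f_base + rule.f_apex)
        else:
            g = rule.f_apex
    return axis.base_mid + g * axis.length_mm * axis.unit


def resample_by_arc(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` points equally spaced in arc length."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, cum[-1], n)
    return np.column_stack(
        [np.interp(target, cum, points[:, 0]), np.interp(target, cum, points[:, 1])]
    )


def correspond_points(
    ed: LaxContour, es: LaxContour, n: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Match ED and ES contour points by equal fractional arc length.

    Both contours are resampled at ``n`` points at equal fractions of their
    own total arc length, measured from the first annulus insertion, and
    paired index-by-index. This deterministic substitute for image-based
    feature tracking is exact for similarity motions of the wall.
    """
    if ed.view != es.view:
        raise ValueError(f"view mismatch: {ed.view.value} vs {es.view.value}")
    if n < MIN_CONTOUR_POINTS:
        raise ValueError(f"need n >= {MIN_CONTOUR_POINTS}, got {n}")
    return resample_by_arc(ed.points, n), resample_by_arc(es.points, n)


def point_inward_displacement(
    p_ed: np.ndarray, p_es: np.ndarray, center: np.ndarray
) -> tuple[float, float]:
    """Inward displacement of one tracked point, in mm and in %.

    Returns ``(ind_mm, ind_pct)`` where ``ind_mm`` is the projection of the
    ED->ES displacement onto the unit vector from the ED point toward the
    centre, and ``ind_pct`` normalises by the ED point-to-centre distance.
    Inward motion is positive, a stationary point scores 0, outward motion
    is negative, and a point that reaches the centre scores 100 %.
    """
    p_ed = np.asarray(p_ed, dtype=float)
    p_es = np.asarray(p_es, dtype=float)
    center = np.asarray(center, dtype=float)
    v = center - p_ed
    d = float(np.linalg.norm(v))
    if d <= _EPS:
        raise ValueError("point coincides with center of contraction")
    u = v / d
    ind_mm = float(np.dot(p_es - p_ed, u))
    return ind_mm, 100.0 * ind_mm / d


@dataclass(frozen=True)
class ViewInD:
    """Per-point inward displacement for all tracked points of one view."""

    view: object
    axis: LvAxis
    p_ed: np.ndarray
    p_es: np.ndarray
    centers: np.ndarray
    fractions: np.ndarray
    ind_mm: np.ndarray
    ind_pct: np.ndarray

    def points(self) -> list[PointInD]:
        return [
            PointInD(
                self.p_ed[i],
                self.p_es[i],
                self.centers[i],
                float(self.fractions[i]),
                float(self.ind_mm[i]),
                float(self.ind_pct[i]),
            )
            for i in range(len(self.ind_mm))
        ]


def compute_view_ind(
    ed: LaxContour,
    es: LaxContour,
    rule: CenterRule = CenterRule(),
    n: int = 200,
    paired: bool = False,
) -> ViewInD:
    """Compute per-point InD for one view.

    With ``paired=True`` the two contours are taken as already tracked
    (index i of ES is the systolic position of index i of ED) and used as
    is; otherwise both are resampled and matched by arc-length fraction.
    """
    axis = fit_axis(ed)
    if paired:
        if ed.points.shape != es.points.shape:
            raise ValueError("paired contours must have identical point counts")
        p_ed, p_es = ed.points, es.points
    else:
        p_ed, p_es = correspond_points(ed, es, n)

    u = axis.unit
    fractions = np.clip((p_ed - axis.base_mid) @ u / axis.length_mm, 0.0, 1.0)
    if rule.mode == "continuous":
        g = rule.f_base + fractions * (rule.f_apex - rule.f_base)
    else:
        g = np.where(
            fractions < 1.0 / 3.0,
            rule.f_base,
            np.where(fractions < 2.0 / 3.0, 0.5 * (rule.f_base + rule.f_apex), rule.f_apex),
        )
    centers = axis.base_mid + g[:, None] * axis.length_mm * u
    to_center = centers - p_ed
    dist = np.linalg.norm(to_center, axis=1)
    if np.any(dist <= _EPS):
        raise ValueError("point coincides with center of contraction")
    unit = to_center / dist[:, None]
    ind_mm = np.einsum("ij,ij->i", p_es - p_ed, unit)
    ind_pct = 100.0 * ind_mm / dist
    return ViewInD(ed.view, axis, p_ed, p_es, centers, fractions, ind_mm, ind_pct)
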