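"""Endocardial contour containers for the three standard long-axis views.

A contour is an ordered, open polyline of 2-D points in millimetres in the
imaging plane. The first point is one mitral-annulus insertion, the last
point is the other, and the traversal passes through the apex. The y axis
increases toward the apex by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

MIN_CONTOUR_POINTS = 20


class View(str, Enum):
    """Standard long-axis imaging planes."""

    CH2 = "2CH"
    CH3 = "3CH"
    CH4 = "4CH"


class Phase(str, Enum):
    """Cardiac phase: end-diastole (maximal filling) / end-systole."""

    ED = "ED"
    ES = "ES"


@dataclass(frozen=True)
class LaxContour:
    """Ordered endocardial polyline for one view and phase.

    Parameters
    ----------
    view : View
        Imaging plane the contour was drawn in.
    phase : Phase
        ED or ES.
    points : (n, 2) ndarray
        Ordered point coordinates in mm; annulus -> apex -> annulus.
    """

    view: View
    phase: Phase
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if pts.shape[0] < MIN_CONTOUR_POINTS:
            raise ValueError(
                f"contour needs >= {MIN_CONTOUR_POINTS} points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour contains non-finite coordinates")
        if np.allclose(pts[0], pts[-1]):
            raise ValueError("contour must be an open polyline (first != last point)")
        object.__setattr__(self, "view", View(self.view))
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "points", pts)
        if self.arc_length() <= 0.0:
            raise ValueError("contour has zero arc length")

    def cumulative_arc(self) -> np.ndarray:
        """Cumulative arc length (mm) at each vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def arc_length(self) -> float:
        return float(self.cumulative_arc()[-1])

    def with_points(self, points: np.ndarray, phase: Phase | None = None) -> "LaxContour":
        return LaxContour(self.view, phase or self.phase, np.asarray(points, dtype=float))
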