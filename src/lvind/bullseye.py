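"""AHA 17-segment bullseye: point-to-segment assignment and three-view fusion.

Each long-axis view cuts two opposite walls of the LV. Each wall runs from
its mitral-annulus insertion to the apex and is split, by wall-arc
fraction, into basal / mid / apical thirds mapping to one AHA segment per
level; the last ``cap_fraction`` of each wall's arc (on both walls, all
views) feeds the apical-cap segment 17. The default view-to-segment
binding follows common vendor triplane conventions and is overridable:

====  ==============  ================  =================
view  wall             segments (b,m,a) notes
====  ==============  ================  =================
4CH   septal           3, 9, 14         first polyline wall
4CH   anterolateral    6, 12, 16
2CH   inferior         4, 10, 15        first polyline wall
2CH   anterior         1, 7, 13
3CH   anteroseptal     2, 8, 13         apical third shared with 2CH
3CH   inferolateral    5, 11, 16        apical third shared with 4CH
====  ==============  ================  =================

Segments 13, 16 and 17 therefore receive contributions from more than one
view and are averaged across views (unweighted by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .contours import View
from .geometry import LvAxis

SEGMENT_NAMES: dict[int, str] = {
    1: "Basal anterior",
    2: "Basal anteroseptal",
    3: "Basal inferoseptal",
    4: "Basal inferior",
    5: "Basal inferolateral",
    6: "Basal anterolateral",
    7: "Mid-anterior",
    8: "Mid-anteroseptal",
    9: "Mid-inferoseptal",
    10: "Mid-inferior",
    11: "Mid-inferolateral",
    12: "Mid-anterolateral",
    13: "Apical anterior",
    14: "Apical septal",
    15: "Apical inferior",
    16: "Apical lateral",
    17: "Apex",
}

BASAL_SEGMENTS = tuple(range(1, 7))
MID_SEGMENTS = tuple(range(7, 13))
APICAL_SEGMENTS = tuple(range(13, 18))
APEX_CAP = 17


@dataclass(frozen=True)
class WallSegments:
    """Basal / mid / apical segment ids of one wall in one view."""

    basal: int
    mid: int
    apical: int

    def at_level(self, level: int) -> int:
        return (self.basal, self.mid, self.apical)[level]


@dataclass(frozen=True)
class ViewSegmentMap:
    """Binding of each view's two walls to AHA segment ids.

    ``walls[view]`` is a pair ``(first_wall, second_wall)`` where the first
    wall is the one containing the first polyline point. ``cap_fraction``
    is the trailing share of each wall's annulus-to-apex arc assigned to
    the apical cap (segment 17); ``level_boundaries`` are the wall-arc
    fractions splitting basal/mid/apical.
    """

    walls: Mapping[View, tuple[WallSegments, WallSegments]]
    cap_fraction: float = 0.10
    level_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.cap_fraction < 0.5):
            raise ValueError("cap_fraction must be in (0, 0.5)")
        b1, b2 = self.level_boundaries
        if not (0.0 < b1 < b2 < 1.0):
            raise ValueError("level boundaries must satisfy 0 < b1 < b2 < 1")
        covered = self.covered_segments()
        if covered != set(range(1, 18)):
            missing = sorted(set(range(1, 18)) - covered)
            raise ValueError(f"view/segment map does not cover segments {missing}")

    def covered_segments(self) -> set[int]:
        ids = {APEX_CAP}
        for first, second in self.walls.values():
            for wall in (first, second):
                ids.update((wall.basal, wall.mid, wall.apical))
        return ids

    def view_segments(self, view: View) -> set[int]:
        first, second = self.walls[view]
        return {APEX_CAP} | {w.at_level(l) for w in (first, second) for l in range(3)}

    @classmethod
    def default(cls, cap_fraction: float = 0.10,
                level_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)) -> "ViewSegmentMap":
        return cls(
            walls={
                View.CH4: (WallSegments(3, 9, 14), WallSegments(6, 12, 16)),
                View.CH2: (WallSegments(4, 10, 15), WallSegments(1, 7, 13)),
                View.CH3: (WallSegments(2, 8, 13), WallSegments(5, 11, 16)),
            },
            cap_fraction=cap_fraction,
            level_boundaries=level_boundaries,
        )


@dataclass(frozen=True)
class SegmentAssignment:
    """Per-point segment id and wall side for one view's sampled points."""

    segment_ids: np.ndarray  # (n,) int
    wall_side: np.ndarray  # (n,) int, 0 = first wall, 1 = second wall
    wall_fraction: np.ndarray  # (n,) annulus->apex arc fraction on own wall


def wall_arc_fractions(p_ed: np.ndarray, axis: LvAxis) -> tuple[np.ndarray, np.ndarray, int]:
    """Split ordered points into two walls at the apex and return, per
    point, its wall side and annulus->apex arc fraction along its wall."""
    dist = np.linalg.norm(p_ed - axis.base_mid, axis=1)
    ia = int(np.argmax(dist))
    seg = np.linalg.norm(np.diff(p_ed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc1 = cum[ia]
    arc2 = cum[-1] - cum[ia]
    if arc1 <= 0.0 or arc2 <= 0.0:
        raise ValueError("degenerate segmentation: a wall has zero arc length")
    side = (np.arange(len(p_ed)) > ia).astype(int)
    frac = np.where(side == 0, cum / arc1, (cum[-1] - cum) / arc2)
    return np.clip(frac, 0.0, 1.0), side, ia


def assign_segments(
    p_ed: np.ndarray, axis: LvAxis, vmap: ViewSegmentMap, view: View
) -> SegmentAssignment:
    """Assign each sampled ED point of one view to an AHA segment."""
    view = View(view)
    frac, side, _ = wall_arc_fractions(np.asarray(p_ed, dtype=float), axis)
    b1, b2 = vmap.level_boundaries
    cap_start = 1.0 - vmap.cap_fraction
    first, second = vmap.walls[view]
    level = np.digitize(frac, [b1, b2])  # 0 basal, 1 mid, 2 apical
    ids = np.empty(len(frac), dtype=int)
    for lv in range(3):
        m = level == lv
        ids[m & (side == 0)] = first.at_level(lv)
        ids[m & (side == 1)] = second.at_level(lv)
    ids[frac >= cap_start] = APEX_CAP
    for s, wall in ((0, "first"), (1, "second")):
        if not np.any((side == s) & (ids != APEX_CAP)):
            raise ValueError(f"degenerate segmentation: {wall} wall empty after cap removal")
    return SegmentAssignment(segment_ids=ids, wall_side=side, wall_fraction=frac)


def segment_means(ind_pct: np.ndarray, assignment: SegmentAssignment) -> dict[int, tuple[float, int]]:
    """Unweighted arithmetic mean of per-point InD within each segment.

    Returns ``{segment_id: (mean_pct, n_points)}`` for the segments the
    view actually sampled.
    """
    ind_pct = np.asarray(ind_pct, dtype=float)
    out: dict[int, tuple[float, int]] = {}
    for sid in np.unique(assignment.segment_ids):
        m = assignment.segment_ids == sid
        out[int(sid)] = (float(ind_pct[m].mean()), int(m.sum()))
    return out


@dataclass(frozen=True)
class RegionMeans:
    base: float
    mid: float
    apex: float
    overall: float

    def rounded(self, decimals: int = 1) -> "RegionMeans":
        return RegionMeans(*(round(v, decimals) for v in (self.base, self.mid, self.apex, self.overall)))

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.base, self.mid, self.apex, self.overall)


def region_averages(seg_pct: np.ndarray | Mapping[int, float], allow_missing: bool = False) -> RegionMeans:
    """Basal (1-6), mid-cavity (7-12), apical (13-17) and overall (1-17)
    arithmetic means of the 17 segmental values."""
    if isinstance(seg_pct, Mapping):
        values = np.array([seg_pct[k] for k in range(1, 18)], dtype=float)
    else:
        values = np.asarray(seg_pct, dtype=float)
    if values.shape != (17,):
        raise ValueError("expected 17 segmental values")
    if not allow_missing and not np.all(np.isfinite(values)):
        raise ValueError("non-finite segmental value")
    mean = np.nanmean if allow_missing else np.mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN region under allow_missing
        return RegionMeans(
            base=float(mean(values[0:6])),
            mid=float(mean(values[6:12])),
            apex=float(mean(values[12:17])),
            overall=float(mean(values)),
        )


@dataclass(frozen=True)
class Bullseye17:
    """Fused 17-segment InD map with per-segment point counts."""

    seg_pct: np.ndarray  # (17,) %, NaN where missing
    n_points: np.ndarray  # (17,) int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seg_pct", np.asarray(self.seg_pct, dtype=float))
        object.__setattr__(self, "n_points", np.asarray(self.n_points, dtype=int))
        if self.seg_pct.shape != (17,) or self.n_points.shape != (17,):
            raise ValueError("Bullseye17 holds exactly 17 segments")

    def __getitem__(self, segment_id: int) -> float:
        return float(self.seg_pct[segment_id - 1])

    @property
    def missing(self) -> list[int]:
        return [i + 1 for i in np.flatnonzero(~np.isfinite(self.seg_pct))]

    def regions(self) -> RegionMeans:
        return region_averages(self.seg_pct, allow_missing=bool(self.missing))


def merge_views(
    per_view: Mapping[View, Mapping[int, tuple[float, int]]],
    weighting: str = "view",
    strict: bool = True,
) -> Bullseye17:
    """Fuse per-view segment means into one bullseye.

    Segments sampled by a single view are copied; shared segments are the
    unweighted mean of the contributing views (``weighting='points'``
    weights each view by its point count instead). With ``strict`` a
    segment covered by no view raises; otherwise it is left NaN.
    """
    if weighting not in ("view", "points"):
        raise ValueError("weighting must be 'view' or 'points'")
    seg = np.full(17, np.nan)
    counts = np.zeros(17, dtype=int)
    for sid in range(1, 18):
        vals, ns = [], []
        for means in per_view.values():
            if sid in means:
                v, n = means[sid]
                vals.append(v)
                ns.append(n)
        if not vals:
            continue
        w = np.asarray(ns, dtype=float) if weighting == "points" else np.ones(len(vals))
        seg[sid - 1] = float(np.average(vals, weights=w))
        counts[sid - 1] = int(sum(ns))
    missing = [i + 1 for i in np.flatnonzero(np.isnan(seg))]
    if missing and strict:
        raise ValueError(f"no view covers segments {missing}")
    return Bullseye17(seg_pct=seg, n_points=counts)
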