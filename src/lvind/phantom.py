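"""Parametric contracting-LV phantom with known ground truth.

The end-diastolic cavity is a half-ellipse (equatorial radius r, base-to-
apex length L) identical in all three long-axis views, with the annulus on
the y = 0 line and the apex at (0, L). Each ED point's end-systolic
position is the ED point moved a fraction s of the way toward its own
centre of contraction (continuous half-to-two-thirds rule), where s is the
contraction fraction of the AHA segment the point belongs to, blended
linearly across segment boundaries over a 5 % arc band so the ES contour
stays smooth. Optional annular descent shifts basal ES points toward the
apex, and optional isotropic Gaussian noise perturbs the emitted ES
points.

Because the construction applies the inward motion directly, the phantom
carries exact ground truth: in ``paired`` output mode (matched ED/ES
indices) the pipeline must reproduce the truth to machine precision; in
``resampled`` mode the ES contour is re-sampled by arc length, so any
discrepancy measures the error of arc-length point correspondence as a
stand-in for feature tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .bullseye import (
    APEX_CAP,
    ViewSegmentMap,
    assign_segments,
    merge_views,
    region_averages,
    segment_means,
    wall_arc_fractions,
)
from .contours import LaxContour, Phase, View
from .geometry import CenterRule, LvAxis, fit_axis, resample_by_arc
from .io import ContourSet
from .metrics import disk_volume, gls_from_contours

_DENSE_N = 1501  # construction density for truth volumes / arc lengths


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``contraction`` is either a single fraction applied everywhere or a
    mapping segment_id -> fraction; fractions live in (-0.5, 0.9] (1 would
    collapse a point onto its centre). ``mode`` selects paired (tracked)
    or resampled (contours-only) output.
    """

    ed_equatorial_radius_mm: float = 22.0
    ed_length_mm: float = 90.0
    contraction: float | Mapping[int, float] = 0.33
    annular_descent_mm: float = 0.0
    noise_sd_mm: float = 0.0
    n_points: int = 200
    seed: int = 0
    mode: str = "paired"
    smoothing_band: float = 0.05  # arc-fraction width of the inter-segment blend

    def __post_init__(self) -> None:
        if self.ed_equatorial_radius_mm <= 0 or self.ed_length_mm <= 0:
            raise ValueError("radius and length must be positive")
        if self.n_points < 20:
            raise ValueError("need n_points >= 20")
        if self.mode not in ("paired", "resampled"):
            raise ValueError("mode must be 'paired' or 'resampled'")
        for sid, s in self.contraction_by_segment().items():
            if s >= 1.0:
                raise ValueError(f"segment {sid}: contraction {s} would cross the center")
            if not (-0.5 < s <= 0.9):
                raise ValueError(f"segment {sid}: contraction {s} outside (-0.5, 0.9]")

    def contraction_by_segment(self) -> dict[int, float]:
        if isinstance(self.contraction, Mapping):
            base = {k: 0.33 for k in range(1, 18)}
            base.update({int(k): float(v) for k, v in self.contraction.items()})
            return base
        return {k: float(self.contraction) for k in range(1, 18)}


@dataclass(frozen=True)
class PhantomTruth:
    """Construction ground truth: segmental InD (%), EF (%) and GLS (%)."""

    seg_ind_pct: np.ndarray  # (17,)
    ef_pct: float
    gls_pct: float
    seed: int

    def regions(self):
        return region_averages(self.seg_ind_pct)


def _half_ellipse(r: float, length: float, n: int) -> np.ndarray:
    """Open half-ellipse from (-r, 0) through (0, L) to (r, 0), sampled at
    ``n`` points of equal arc length."""
    t = np.linspace(0.0, np.pi, 4 * n + 1)
    dense = np.column_stack([-r * np.cos(t), length * np.sin(t)])
    return resample_by_arc(dense, n)


def _blended_fraction_profile(
    wall_frac: np.ndarray,
    side: np.ndarray,
    s_by_segment: Mapping[int, float],
    vmap: ViewSegmentMap,
    view: View,
    band: float,
) -> np.ndarray:
    """Per-point applied contraction fraction: the segment's s, blended
    linearly across level/cap boundaries over ``band`` of wall arc."""
    b1, b2 = vmap.level_boundaries
    cap = 1.0 - vmap.cap_fraction
    h = band / 2.0
    first, second = vmap.walls[view]
    out = np.empty_like(wall_frac)
    for s_idx, wall in ((0, first), (1, second)):
        vals = [s_by_segment[wall.basal], s_by_segment[wall.mid],
                s_by_segment[wall.apical], s_by_segment[APEX_CAP]]
        xp = [0.0, b1 - h, b1 + h, b2 - h, b2 + h, cap - h, cap + h, 1.0]
        yp = [vals[0], vals[0], vals[1], vals[1], vals[2], vals[2], vals[3], vals[3]]
        m = side == s_idx
        out[m] = np.interp(wall_frac[m], xp, yp)
    return out


def _move_toward_center(
    pts: np.ndarray, axis: LvAxis, s: np.ndarray, rule: CenterRule, descent_mm: float
) -> np.ndarray:
    u = axis.unit
    f = np.clip((pts - axis.base_mid) @ u / axis.length_mm, 0.0, 1.0)
    g = rule.f_base + f * (rule.f_apex - rule.f_base)
    centers = axis.base_mid + g[:, None] * axis.length_mm * u
    es = pts + s[:, None] * (centers - pts)
    if descent_mm != 0.0:
        es = es + descent_mm * (1.0 - f)[:, None] * u
    return es


def generate_phantom(
    spec: PhantomSpec,
    vmap: ViewSegmentMap | None = None,
    rule: CenterRule = CenterRule(),
) -> tuple[ContourSet, PhantomTruth]:
    """Build the three-view ED/ES contour set and its ground truth.

    The same seed always yields bit-identical output. Truth segmental InD
    is computed from the noise-free paired construction (per point,
    100 * inward component / ED-point-to-centre distance, averaged per
    segment per view, views fused like the pipeline); truth EF and GLS
    come from a dense noise-free construction integrated with a fine disk
    stack.
    """
    vmap = vmap or ViewSegmentMap.default()
    s_by_seg = spec.contraction_by_segment()
    rng = np.random.default_rng(spec.seed)

    ed_pts = _half_ellipse(spec.ed_equatorial_radius_mm, spec.ed_length_mm, spec.n_points)
    ed_dense = _half_ellipse(spec.ed_equatorial_radius_mm, spec.ed_length_mm, _DENSE_N)

    contours: dict[tuple[View, Phase], LaxContour] = {}
    per_view_truth: dict[View, dict[int, tuple[float, int]]] = {}
    ed_map: dict[View, LaxContour] = {}
    es_dense_map: dict[View, LaxContour] = {}

    for view in (View.CH2, View.CH3, View.CH4):
        ed_contour = LaxContour(view, Phase.ED, ed_pts)
        axis = fit_axis(ed_contour)

        def applied_fraction(points: np.ndarray) -> np.ndarray:
            frac, side, _ = wall_arc_fractions(points, axis)
            return _blended_fraction_profile(
                frac, side, s_by_seg, vmap, view, spec.smoothing_band
            )

        s_out = applied_fraction(ed_pts)
        es0 = _move_toward_center(ed_pts, axis, s_out, rule, spec.annular_descent_mm)

        # truth from the noise-free paired construction
        u = axis.unit
        f = np.clip((ed_pts - axis.base_mid) @ u / axis.length_mm, 0.0, 1.0)
        g = rule.f_base + f * (rule.f_apex - rule.f_base)
        centers = axis.base_mid + g[:, None] * axis.length_mm * u
        to_c = centers - ed_pts
        dist = np.linalg.norm(to_c, axis=1)
        true_pct = 100.0 * np.einsum("ij,ij->i", es0 - ed_pts, to_c / dist[:, None]) / dist
        assignment = assign_segments(ed_pts, axis, vmap, view)
        per_view_truth[view] = segment_means(true_pct, assignment)

        # dense noise-free construction for truth EF / GLS
        s_dense = applied_fraction(ed_dense)
        es_dense = _move_toward_center(ed_dense, axis, s_dense, rule, spec.annular_descent_mm)
        ed_map[view] = LaxContour(view, Phase.ED, ed_dense)
        es_dense_map[view] = LaxContour(view, Phase.ES, es_dense)

        if spec.mode == "resampled":
            es_pts = resample_by_arc(es0, spec.n_points)
        else:
            es_pts = es0
        if spec.noise_sd_mm > 0.0:
            es_pts = es_pts + rng.normal(0.0, spec.noise_sd_mm, es_pts.shape)
        contours[(view, Phase.ED)] = ed_contour
        contours[(view, Phase.ES)] = LaxContour(view, Phase.ES, es_pts)

    truth_bullseye = merge_views(per_view_truth, weighting="view", strict=True)
    edv = disk_volume(list(ed_map.values()), n_disks=1000)
    esv = disk_volume(list(es_dense_map.values()), n_disks=1000)
    gls, _ = gls_from_contours(ed_map, es_dense_map)
    truth = PhantomTruth(
        seg_ind_pct=truth_bullseye.seg_pct,
        ef_pct=100.0 * (edv - esv) / edv,
        gls_pct=gls,
        seed=spec.seed,
    )
    subject = ContourSet(
        subject_id=f"phantom-{spec.seed}",
        contours=contours,
        paired=(spec.mode == "paired"),
    )
    return subject, truth


def simulate_observers(
    contour_set: ContourSet, jitter_sd_mm: float, seed: int
) -> ContourSet:
    """Emulate a second observer's manual contour corrections by adding
    seeded isotropic Gaussian jitter to every contour point (both phases,
    all views). Deterministic per seed; index pairing is preserved."""
    rng = np.random.default_rng(seed)
    perturbed = {}
    for key, contour in contour_set.contours.items():
        pts = contour.points
        if jitter_sd_mm > 0.0:
            pts = pts + rng.normal(0.0, jitter_sd_mm, pts.shape)
        perturbed[key] = LaxContour(contour.view, contour.phase, pts)
    return ContourSet(
        subject_id=f"{contour_set.subject_id}-observer{seed}",
        contours=perturbed,
        paired=contour_set.paired,
    )
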