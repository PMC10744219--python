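"""Axis fitting, centre-of-contraction rule and per-point inward displacement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvind.contours import LaxContour, Phase, View
from lvind.geometry import (
    CenterRule,
    LvAxis,
    compute_view_ind,
    contraction_center,
    correspond_points,
    fit_axis,
    longitudinal_fraction,
    point_inward_displacement,
    resample_by_arc,
)
from lvind.phantom import _half_ellipse


def make_contour(points, view=View.CH2, phase=Phase.ED):
    return LaxContour(view, phase, np.asarray(points, dtype=float))


@pytest.fixture()
def ellipse():
    return make_contour(_half_ellipse(20.0, 90.0, 201))


class TestFitAxis:
    def test_symmetric_half_ellipse(self, ellipse):
        axis = fit_axis(ellipse)
        assert np.allclose(axis.base_mid, [0.0, 0.0], atol=1e-9)
        assert np.allclose(axis.apex, [0.0, 90.0], atol=0.05)
        assert axis.length_mm == pytest.approx(90.0, abs=0.05)

    def test_translation_equivariance(self, ellipse):
        axis = fit_axis(ellipse)
        shifted = fit_axis(make_contour(ellipse.points + [5.0, 5.0]))
        assert np.allclose(shifted.base_mid, axis.base_mid + [5.0, 5.0])
        assert np.allclose(shifted.apex, axis.apex + [5.0, 5.0])
        assert shifted.length_mm == pytest.approx(axis.length_mm)

    def test_off_axis_apex_distance(self):
        # annuli at (+/-20, 0) with farthest point at (10, 80)
        t = np.linspace(0, np.pi, 101)
        pts = np.column_stack([-20 * np.cos(t), 60 * np.sin(t)])
        pts[50] = [10.0, 80.0]
        axis = fit_axis(make_contour(pts))
        assert axis.length_mm == pytest.approx(np.hypot(10.0, 80.0))  # ~80.62 mm

    def test_degenerate_contour_rejected(self):
        pts = np.tile([1.0, 1.0], (25, 1))
        pts[-1] = [1.0, 1.0 + 1e-12]
        with pytest.raises(ValueError):
            make_contour(pts)


class TestLongitudinalFraction:
    axis = LvAxis(base_mid=np.array([0.0, 0.0]), apex=np.array([0.0, 90.0]), length_mm=90.0)

    @pytest.mark.parametrize(
        "point,expected",
        [([0.0, 0.0], 0.0), ([0.0, 90.0], 1.0), ([15.0, 45.0], 0.5), ([0.0, -3.0], 0.0)],
    )
    def test_projection_clamped(self, point, expected):
        assert longitudinal_fraction(np.array(point), self.axis) == pytest.approx(expected)


class TestContractionCenter:
    axis = LvAxis(base_mid=np.array([0.0, 0.0]), apex=np.array([0.0, 90.0]), length_mm=90.0)

    @pytest.mark.parametrize(
        "f,expected_y", [(0.0, 45.0), (1.0, 60.0), (0.5, 52.5)]
    )
    def test_continuous_half_to_two_thirds(self, f, expected_y):
        c = contraction_center(f, self.axis)
        assert np.allclose(c, [0.0, expected_y])

    def test_discrete3_levels(self):
        rule = CenterRule(mode="discrete3")
        ys = [contraction_center(f, self.axis, rule)[1] for f in (0.1, 0.5, 0.9)]
        assert ys == pytest.approx([45.0, 52.5, 60.0])

    def test_monotone_in_fraction(self):
        fs = np.linspace(0, 1, 50)
        ys = [contraction_center(f, self.axis)[1] for f in fs]
        assert np.all(np.diff(ys) >= 0)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            CenterRule(f_base=0.7, f_apex=0.6)


class TestCorrespondPoints:
    def test_identical_contours_zero_displacement(self, ellipse):
        es = LaxContour(ellipse.view, Phase.ES, ellipse.points.copy())
        p_ed, p_es = correspond_points(ellipse, es, n=57)
        assert np.allclose(p_ed, p_es, atol=1e-9)

    def test_equal_arc_spacing_on_straight_line(self):
        pts = np.column_stack([np.zeros(21), np.linspace(0, 100, 21) ** 1.0])
        # non-uniform vertex spacing, same geometry
        warped = np.column_stack([np.zeros(21), 100 * np.linspace(0, 1, 21) ** 2])
        rs = resample_by_arc(warped, 5)
        assert np.allclose(rs[:, 1], [0, 25, 50, 75, 100], atol=1e-9)
        del pts

    def test_similarity_scaling_preserves_pairing(self, ellipse):
        es = LaxContour(ellipse.view, Phase.ES, ellipse.points * 0.8)
        p_ed, p_es = correspond_points(ellipse, es, n=50)
        assert np.allclose(p_es, 0.8 * p_ed, atol=1e-8)

    def test_view_mismatch_and_small_n_rejected(self, ellipse):
        other = LaxContour(View.CH4, Phase.ES, ellipse.points)
        with pytest.raises(ValueError):
            correspond_points(ellipse, other)
        es = LaxContour(ellipse.view, Phase.ES, ellipse.points)
        with pytest.raises(ValueError):
            correspond_points(ellipse, es, n=10)


class TestPointInwardDisplacement:
    @pytest.mark.parametrize(
        "p_es,expected_mm,expected_pct",
        [
            ([20.0, 0.0], 20.0, 50.0),  # halfway to the centre
            ([40.0, 0.0], 0.0, 0.0),  # akinetic
            ([50.0, 0.0], -10.0, -25.0),  # dyskinetic, outward
            ([0.0, 0.0], 40.0, 100.0),  # reaches the centre
        ],
    )
    def test_sign_and_normalisation(self, p_es, expected_mm, expected_pct):
        mm, pct = point_inward_displacement(
            np.array([40.0, 0.0]), np.array(p_es), np.array([0.0, 0.0])
        )
        assert mm == pytest.approx(expected_mm)
        assert pct == pytest.approx(expected_pct)

    def test_point_at_center_rejected(self):
        with pytest.raises(ValueError, match="center of contraction"):
            point_inward_displacement(np.zeros(2), np.ones(2), np.zeros(2))

    def test_antisymmetric_under_reflection(self):
        p_ed = np.array([30.0, 10.0])
        c = np.array([5.0, 40.0])
        u = (c - p_ed) / np.linalg.norm(c - p_ed)
        inward = p_ed + 7.0 * u
        outward = p_ed - 7.0 * u
        _, pct_in = point_inward_displacement(p_ed, inward, c)
        _, pct_out = point_inward_displacement(p_ed, outward, c)
        assert pct_in == pytest.approx(-pct_out)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    angle=st.floats(0.0, 2 * np.pi),
    tx=st.floats(-100.0, 100.0),
    ty=st.floats(-100.0, 100.0),
)
def test_ind_invariant_under_rigid_motion(angle, tx, ty):
    """Rotating + translating all inputs leaves every InD value unchanged."""
    ed_pts = _half_ellipse(22.0, 90.0, 80)
    es_pts = ed_pts * 0.7 + [0.0, 10.0]
    ed = LaxContour(View.CH3, Phase.ED, ed_pts)
    es = LaxContour(View.CH3, Phase.ES, es_pts)
    base = compute_view_ind(ed, es, paired=True)

    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    t = np.array([tx, ty])
    ed_r = LaxContour(View.CH3, Phase.ED, ed_pts @ R.T + t)
    es_r = LaxContour(View.CH3, Phase.ES, es_pts @ R.T + t)
    moved = compute_view_ind(ed_r, es_r, paired=True)
    assert np.allclose(moved.ind_mm, base.ind_mm, atol=1e-8)
    assert np.allclose(moved.ind_pct, base.ind_pct, atol=1e-8)


def test_fractional_motion_analytic_oracle():
    """Moving every ED point fraction s toward its own centre gives
    ind_pct = 100 s for every point, to machine precision."""
    ed_pts = _half_ellipse(22.0, 90.0, 120)
    ed = LaxContour(View.CH2, Phase.ED, ed_pts)
    probe = compute_view_ind(ed, LaxContour(View.CH2, Phase.ES, ed_pts), paired=True)
    for s in (0.1, 0.33, 0.5, -0.1):
        es_pts = ed_pts + s * (probe.centers - ed_pts)
        res = compute_view_ind(ed, LaxContour(View.CH2, Phase.ES, es_pts), paired=True)
        assert np.allclose(res.ind_pct, 100.0 * s, atol=1e-10)
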