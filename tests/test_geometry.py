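"""Contour morphometrics: midline, width, length, pill volume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from osmofit.geometry import (
    Contour,
    cell_length,
    cell_width,
    compute_midline,
    pill_volume,
    shape_from_contour,
    spherocylinder_boundary,
)
from osmofit.errors import ParameterError


def make_contour(radius=0.5, length=3.0, n=96, angle=0.0, offset=(0.0, 0.0)):
    pts, _ = spherocylinder_boundary(radius, length, n)
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return Contour(points=pts @ rot.T + np.asarray(offset))


class TestPillVolume:
    def test_sphere_limit_same_under_both_formulas(self):
        for formula in ("spherocylinder", "printed"):
            v = pill_volume(1.0, 1.0, formula=formula)
            assert v == pytest.approx(4.0 / 3.0 * math.pi * 0.5 ** 3)

    def test_hand_value(self):
        # R=0.5, L=3: pi*0.25*2 + (4/3)*pi*0.125
        assert pill_volume(1.0, 3.0) == pytest.approx(2.0944, abs=1e-4)

    def test_printed_variant_doubles_cylinder_term(self):
        default = pill_volume(1.0, 3.0)
        printed = pill_volume(1.0, 3.0, formula="printed")
        assert printed - default == pytest.approx(math.pi * 0.25 * 2.0)

    def test_matches_solid_of_revolution_quadrature(self):
        for R, L in [(0.3, 1.5), (0.5, 3.0), (0.7, 5.0)]:
            c = L / 2 - R

            def r2(x):
                ax = abs(x)
                if ax <= c:
                    return R * R
                return max(R * R - (ax - c) ** 2, 0.0)

            v_num = math.pi * quad(r2, -L / 2, L / 2,
                                   points=[-c, c], limit=200)[0]
            assert pill_volume(2 * R, L) == pytest.approx(v_num, rel=1e-3)

    def test_length_shorter_than_width_rejected(self):
        with pytest.raises(ParameterError):
            pill_volume(2.0, 1.0)

    @given(st.floats(min_value=0.3, max_value=0.7),
           st.floats(min_value=0.3, max_value=0.7),
           st.floats(min_value=1.5, max_value=5.0),
           st.floats(min_value=1.5, max_value=5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_radius_and_length(self, r1, r2, l1, l2):
        ra, rb = sorted((r1, r2))
        la, lb = sorted((l1, l2))
        assert pill_volume(2 * ra, la) <= pill_volume(2 * rb, la) + 1e-12
        assert pill_volume(2 * ra, la) <= pill_volume(2 * ra, lb) + 1e-12


class TestMidline:
    def test_spherocylinder_midline_spans_pole_to_pole(self):
        c = make_contour(0.5, 3.0)
        m = compute_midline(c)
        assert not m.degenerate
        assert m.length == pytest.approx(3.0, rel=0.01)
        # straight axis: endpoints at the cap tips
        assert m.points[0][0] == pytest.approx(-1.5, abs=0.01) or \
            m.points[0][0] == pytest.approx(1.5, abs=0.01)

    def test_rotation_equivariance(self):
        angle = math.radians(37.0)
        m0 = compute_midline(make_contour())
        m1 = compute_midline(make_contour(angle=angle))
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        expected = m0.points @ rot.T
        got = m1.points
        if np.linalg.norm(got[0] - expected[0]) > np.linalg.norm(
                got[0] - expected[-1]):
            got = got[::-1]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    @pytest.mark.parametrize("phi", [0.15, 0.35, 0.45])
    def test_bent_rod_midline_tracks_generating_arc(self, phi):
        # banana: centerline is a circular arc of radius rho, half-angle phi,
        # capped by semicircles swept outward through each tip
        rho, R = 4.0, 0.4
        th = np.linspace(-phi, phi, 60)
        center = np.column_stack([rho * np.sin(th), rho * (np.cos(th) - 1)])
        normal = np.column_stack([np.sin(th), np.cos(th)])  # outward of bend
        outer = center + R * normal
        inner = (center - R * normal)[::-1]

        def cap(at, travel):
            t_ang = math.atan2(travel[1], travel[0])
            a = np.linspace(t_ang + math.pi / 2, t_ang - math.pi / 2, 20)
            return at + R * np.column_stack([np.cos(a), np.sin(a)])

        travel_end = np.array([math.cos(phi), -math.sin(phi)])
        travel_start = -np.array([math.cos(phi), math.sin(phi)])
        pts = np.vstack([outer, cap(center[-1], travel_end)[1:-1], inner,
                         cap(center[0], travel_start)[1:-1]])
        contour = Contour(points=pts)
        assert contour.is_simple()
        m = compute_midline(contour, n_stations=40)
        truth = 2 * rho * phi + 2 * R   # arc length plus the two cap tips
        assert m.length == pytest.approx(truth, rel=0.02)
        assert cell_width(contour, m) == pytest.approx(2 * R, rel=0.02)

    def test_round_blob_flagged_degenerate(self):
        a = np.linspace(0, 2 * math.pi, 40, endpoint=False)
        c = Contour(points=np.column_stack([np.cos(a), 1.02 * np.sin(a)]))
        assert compute_midline(c).degenerate


class TestWidth:
    def test_spherocylinder_width(self):
        c = make_contour(0.5, 3.0)
        assert cell_width(c, compute_midline(c)) == pytest.approx(1.0,
                                                                  rel=0.01)

    def test_homogeneity_under_uniform_scaling(self):
        c1 = make_contour(0.5, 3.0)
        c2 = Contour(points=2.0 * c1.points)
        w1 = cell_width(c1, compute_midline(c1))
        w2 = cell_width(c2, compute_midline(c2))
        assert w2 == pytest.approx(2.0 * w1, rel=1e-9)

    def test_septal_constriction_excluded(self):
        # pinch the mid-cell region of an exact spherocylinder by 40%
        pts, _ = spherocylinder_boundary(0.5, 4.0, 192)
        x = pts[:, 0]
        pinch = 1.0 - 0.4 * np.exp(-(x / 0.25) ** 2)
        c = Contour(points=np.column_stack([x, pts[:, 1] * pinch]))
        m = compute_midline(c)
        assert cell_width(c, m) == pytest.approx(1.0, rel=0.02)


class TestShapeFromContour:
    def test_noise_free_recovery(self):
        s = shape_from_contour(make_contour(0.5, 3.0))
        assert s.width == pytest.approx(1.0, rel=0.01)
        assert s.length == pytest.approx(3.0, rel=0.01)
        assert s.volume == pytest.approx(2.0944, rel=0.01)
        assert not s.degenerate

    def test_planted_grid_recovery_within_one_percent(self):
        for R in (0.3, 0.5, 0.7):
            for L in (1.5, 3.0, 5.0):
                if L < 2 * R * 1.1:
                    continue
                s = shape_from_contour(make_contour(R, L))
                assert s.width == pytest.approx(2 * R, rel=0.01)
                assert s.length == pytest.approx(L, rel=0.01)
                assert s.volume == pytest.approx(pill_volume(2 * R, L),
                                                 rel=0.01)

    def test_rigid_motion_invariance(self):
        s0 = shape_from_contour(make_contour())
        s1 = shape_from_contour(make_contour(angle=1.1, offset=(7.0, -3.0)))
        assert abs(s1.width - s0.width) < 1e-9
        assert abs(s1.length - s0.length) < 1e-9
        assert abs(s1.volume - s0.volume) < 1e-9

    def test_scaling_homogeneity_of_volume(self):
        s1 = shape_from_contour(make_contour(0.4, 2.5))
        s2 = shape_from_contour(Contour(points=1.7 * make_contour(0.4, 2.5).points))
        assert s2.volume == pytest.approx(1.7 ** 3 * s1.volume, rel=1e-9)

    def test_jittered_contours_have_small_bias(self):
        from osmofit import CellPopSimParams, simulate_cell_population
        p = CellPopSimParams(n_cells=40, sd_rate=0.0, mean_width=1.0,
                             cv_width=0.0, mean_length=3.0, cv_length=0.0,
                             contour_noise=0.02, seed=7)
        contours, _ = simulate_cell_population(p)
        shapes = [shape_from_contour(c) for c in contours]
        mean_w = np.mean([s.width for s in shapes])
        mean_l = np.mean([s.length for s in shapes])
        assert abs(mean_w - 1.0) < 0.03
        assert abs(mean_l - 3.0) / 3.0 < 0.03

    def test_round_blob_flagged(self):
        a = np.linspace(0, 2 * math.pi, 48, endpoint=False)
        c = Contour(points=np.column_stack([1.01 * np.cos(a), np.sin(a)]))
        assert shape_from_contour(c).degenerate
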