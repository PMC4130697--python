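"""Unit tests for the planar construction: points A, B, C, D, the two
measurement rules, the concave-pedicle fallback, wedge substitution and the
small-angle linearisation error."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rect_landmarks
from vertrot.errors import (
    DegenerateGeometryError,
    MissingLandmarkError,
    UnmeasurableError,
    ValidationError,
)
from vertrot.geometry import (
    LandmarkSet,
    Point2D,
    base_foot_C,
    body_center_A,
    concave_fallback,
    intersect_diagonals,
    measure_rotation,
    pedicle_midpoint_B,
    rule_for_level,
    small_angle_error,
    thoracic_point_D,
    wedge_substitute,
)


class TestIntersectDiagonals:
    @pytest.mark.parametrize(
        "quad, expected",
        [
            # symmetric cases
            ([(0, 0), (1, 0), (1, 1), (0, 1)], (0.5, 0.5)),
            ([(0, 0), (4, 0), (4, 2), (0, 2)], (2.0, 1.0)),
            # frozen from the line-equation oracle: diagonals (0,0)-(3,2) and
            # (4,0)-(1,2) meet at x=2 (symmetry), y=2*(2/3)=4/3
            ([(0, 0), (4, 0), (3, 2), (1, 2)], (2.0, 4.0 / 3.0)),
            ([(0, 0), (30, 0), (34, 24), (4, 24)], (17.0, 12.0)),
        ],
    )
    def test_known_quads(self, quad, expected):
        p = intersect_diagonals(quad)
        assert p.x == pytest.approx(expected[0], abs=1e-12)
        assert p.y == pytest.approx(expected[1], abs=1e-12)

    def test_matches_shapely_oracle(self):
        shapely = pytest.importorskip("shapely")
        rng = np.random.default_rng(7)
        for _ in range(50):
            base = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)
            quad = base * rng.uniform(10, 40) + rng.normal(0, 2, size=(4, 2))
            d1, d2 = quad[2] - quad[0], quad[3] - quad[1]
            if abs(d1[0] * d2[1] - d1[1] * d2[0]) < 1e-6:
                continue
            inter = shapely.LineString([quad[0], quad[2]]).intersection(
                shapely.LineString([quad[1], quad[3]])
            )
            if inter.is_empty or inter.geom_type != "Point":
                continue
            ours = intersect_diagonals([tuple(p) for p in quad])
            assert ours.x == pytest.approx(inter.x, abs=1e-9)
            assert ours.y == pytest.approx(inter.y, abs=1e-9)

    @pytest.mark.parametrize(
        "quad",
        [
            [(0, 0), (1, 0), (2, 0), (3, 0)],  # collinear, zero area
            [(0, 0), (1, 0), (1, 1e-12), (0, 1e-12)],  # area below tolerance
        ],
    )
    def test_degenerate(self, quad):
        with pytest.raises(DegenerateGeometryError):
            intersect_diagonals(quad)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            intersect_diagonals([(0, 0), (1, 0), (float("nan"), 1), (0, 1)])


class TestConstructionPoints:
    def test_A_symmetric_rectangle_on_midline(self):
        ls = rect_landmarks(width=40, height=30)
        assert body_center_A(ls).x == pytest.approx(0.0, abs=1e-12)

    def test_A_rhomboid(self):
        ls = LandmarkSet(
            "L2",
            (Point2D(0, 0), Point2D(30, 0), Point2D(34, 24), Point2D(4, 24)),
            Point2D(10, 12),
            Point2D(22, 12),
        )
        a = body_center_A(ls)
        assert (a.x, a.y) == pytest.approx((17.0, 12.0), abs=1e-12)

    def test_A_drifts_toward_wedge_apex(self):
        # left side shorter (apex left): centre must sit left of the base midpoint
        ls = LandmarkSet(
            "Th6",
            (Point2D(0, 0), Point2D(30, 0), Point2D(30, 30), Point2D(0, 24)),
            Point2D(9, 10),
            Point2D(21, 10),
        )
        assert body_center_A(ls).x < 15.0

    def test_B_symmetric(self):
        ls = rect_landmarks(width=40, height=30, ped_x=(-8, 8))
        b = pedicle_midpoint_B(ls)
        assert (b.x, b.y) == pytest.approx((0.0, 15.0), abs=1e-12)

    def test_B_asymmetric_rectangle_closed_form(self):
        ls = rect_landmarks(width=60, height=30, ped_x=(-8, 12))
        b = pedicle_midpoint_B(ls)
        assert (b.x, b.y) == pytest.approx((2.0, 15.0), abs=1e-12)

    def test_B_rhomboid_matches_diagonal_oracle(self):
        # slanted top edge: brute-force the constructed quadrangle's diagonals
        quad = (Point2D(0, 0), Point2D(30, 0), Point2D(34, 26), Point2D(4, 22))
        ls = LandmarkSet("L3", quad, Point2D(10, 11), Point2D(22, 11))

        def top_y(x):  # top edge from (4,22) to (34,26)
            return 22 + (x - 4) * (26 - 22) / 30

        xl, xr = 10.0, 22.0
        corners = [(xl, 0), (xr, 0), (xr, top_y(xr)), (xl, top_y(xl))]
        expected = intersect_diagonals(corners)
        b = pedicle_midpoint_B(ls)
        assert (b.x, b.y) == pytest.approx((expected.x, expected.y), abs=1e-9)

    def test_B_requires_both_pedicles(self):
        ls = rect_landmarks(missing="left")
        ls = LandmarkSet(
            ls.level, ls.body_quad, None, ls.pedicle_right_inner,
            concave_pedicle_missing="left",
        )
        with pytest.raises(MissingLandmarkError):
            pedicle_midpoint_B(ls)

    def test_C_axis_aligned(self):
        ls = rect_landmarks(width=40, height=30)
        c = base_foot_C(Point2D(2, 1), ls)
        assert (c.x, c.y) == pytest.approx((2.0, 0.0), abs=1e-12)

    def test_C_rotated_base_projection(self):
        # base rotated 10 deg in-plane: |AC| = point-line distance to the base
        th = math.radians(10)
        c, s = math.cos(th), math.sin(th)

        def rot(x, y):
            return Point2D(c * x - s * y, s * x + c * y)

        quad = (rot(0, 0), rot(40, 0), rot(40, 30), rot(0, 30))
        ls = LandmarkSet("L1", quad, rot(12, 15), rot(28, 15))
        a = rot(13.0, 17.0)
        foot = base_foot_C(a, ls)
        dist = math.hypot(foot.x - a.x, foot.y - a.y)
        # distance from A to the base line through origin with direction u
        u = np.array([c, s])
        v = np.array([a.x, a.y])
        expected = abs(v[0] * (-u[1]) + v[1] * u[0])
        assert dist == pytest.approx(expected, abs=1e-12)

    def test_C_identity_on_base(self):
        ls = rect_landmarks()
        c = base_foot_C(Point2D(-3.0, 0.0), ls)
        assert (c.x, c.y) == pytest.approx((-3.0, 0.0), abs=1e-12)

    def test_D_three_quarters_height(self):
        ls = rect_landmarks(level="Th6", width=40, height=40)
        d = thoracic_point_D(Point2D(5.0, 20.0), ls)
        assert (d.x, d.y) == pytest.approx((5.0, 30.0), abs=1e-12)

    def test_D_on_top_edge_is_fixed_point(self):
        ls = rect_landmarks(level="Th6", width=40, height=40)
        d = thoracic_point_D(Point2D(5.0, 40.0), ls)
        assert (d.x, d.y) == pytest.approx((5.0, 40.0), abs=1e-12)

    def test_D_slanted_top_oracle(self):
        quad = (Point2D(0, 0), Point2D(30, 0), Point2D(30, 28), Point2D(0, 22))
        ls = LandmarkSet("Th8", quad, Point2D(9, 10), Point2D(21, 10))
        b = Point2D(12.0, 11.0)
        top_y = 22 + 12.0 * (28 - 22) / 30  # top edge at x = 12
        d = thoracic_point_D(b, ls)
        assert (d.x, d.y) == pytest.approx((12.0, (11.0 + top_y) / 2), abs=1e-12)

    def test_perpendicular_beyond_extension_is_degenerate(self):
        ls = rect_landmarks(width=40, height=30)
        far = Point2D(500.0, 15.0)  # way past the body: edge hit beyond 2x diagonal
        with pytest.raises(DegenerateGeometryError):
            thoracic_point_D(far, ls)


class TestMeasureRotation:
    def test_symmetric_is_zero(self):
        for level in ("L2", "Th6", "L5"):
            ls = rect_landmarks(level=level, width=40, height=30, ped_x=(-8, 8))
            assert measure_rotation(ls).alpha_deg == pytest.approx(0.0, abs=1e-12)

    def test_lumbar_closed_form_20deg(self):
        # z = 30, offset d = 0.5*z*tan(20): the rule reads back exactly 20
        z, d = 30.0, 15.0 * math.tan(math.radians(20.0))
        ls = rect_landmarks(level="L2", width=60, height=z, ped_x=(-8 + d, 8 + d))
        res = measure_rotation(ls)
        assert res.rule == "lumbar" and res.k == 0.5
        assert res.alpha_deg == pytest.approx(20.0, abs=1e-9)
        assert res.d_mm == pytest.approx(d, abs=1e-9)
        assert res.z_mm == pytest.approx(z, abs=1e-9)

    def test_thoracic_closed_form_21deg(self):
        # z = 40, d = 0.75*z*tan(21): the 21-deg leg crosses at 3/4 height
        z, d = 40.0, 30.0 * math.tan(math.radians(21.0))
        ls = rect_landmarks(level="Th6", width=80, height=z, ped_x=(-9 + d, 9 + d))
        res = measure_rotation(ls)
        assert res.rule == "thoracic" and res.k == 0.75
        assert res.alpha_deg == pytest.approx(21.0, abs=1e-9)
        assert res.D is not None

    def test_L5_uses_thoracic_rule(self):
        assert rule_for_level("L5") == "thoracic"
        assert rule_for_level("l4") == "lumbar"
        assert rule_for_level("Th12") == "thoracic"

    def test_sign_convention(self):
        z = 30.0
        d = 15.0 * math.tan(math.radians(10.0))
        plus = rect_landmarks(level="L2", width=60, height=z, ped_x=(-8 + d, 8 + d))
        minus = rect_landmarks(level="L2", width=60, height=z, ped_x=(-8 - d, 8 - d))
        assert measure_rotation(plus).alpha_deg == pytest.approx(10.0, abs=1e-9)
        assert measure_rotation(minus).alpha_deg == pytest.approx(-10.0, abs=1e-9)

    def test_over_30_flagged_not_fatal(self):
        z = 30.0
        d = 15.0 * math.tan(math.radians(35.0))
        ls = rect_landmarks(level="L2", width=80, height=z, ped_x=(-8 + d, 8 + d))
        res = measure_rotation(ls)
        assert res.alpha_deg == pytest.approx(35.0, abs=1e-9)
        assert res.over_limit and "over-30deg" in res.flags

    def test_missing_pedicle_without_flag_errors(self):
        ls = rect_landmarks()
        broken = LandmarkSet(
            ls.level, ls.body_quad, None, ls.pedicle_right_inner,
            concave_pedicle_missing="left",
        )
        ok = measure_rotation(broken)  # flagged: fallback applies
        assert "concave-fallback" in ok.flags
        with pytest.raises(MissingLandmarkError):
            LandmarkSet(ls.level, ls.body_quad, None, ls.pedicle_right_inner).validate()


class TestConcaveFallback:
    def test_flag_none_is_identity(self):
        ls = rect_landmarks()
        assert concave_fallback(ls) is ls

    def test_left_replacement_on_rectangle(self):
        # visible right pedicle at 40% height: replacement on the left edge
        # at the same fraction
        ls = rect_landmarks(width=40, height=30, ped_x=(-8, 8), ped_h_frac=0.4,
                            missing="left")
        out = concave_fallback(ls)
        p = out.pedicle_left_inner
        assert (p.x, p.y) == pytest.approx((-20.0, 12.0), abs=1e-12)
        assert out.pedicle_right_inner == ls.pedicle_right_inner

    def test_both_missing_unmeasurable(self):
        ls = rect_landmarks(missing="left")
        broken = LandmarkSet(
            ls.level, ls.body_quad, ls.pedicle_left_inner, None,
            concave_pedicle_missing="left",
        )
        with pytest.raises(UnmeasurableError):
            concave_fallback(broken)


class TestWedgeSubstitute:
    def test_rectangle_idempotent(self):
        rect = [(0, 0), (30, 0), (30, 24), (0, 24)]
        quad, ambiguous = wedge_substitute(rect, (1, 0))
        assert ambiguous  # equal heights: bounding parallelogram path
        got = sorted((p.x, p.y) for p in quad)
        assert got == pytest.approx(sorted(rect))

    def test_wedged_quad_takes_convex_height(self):
        contour = [(0, 0), (30, 0), (30, 30), (0, 24)]
        quad, ambiguous = wedge_substitute(contour, (1, 0))
        assert not ambiguous
        ys = sorted({round(p.y, 9) for p in quad})
        assert ys == pytest.approx([0.0, 30.0])
        xs = sorted({round(p.x, 9) for p in quad})
        assert xs == pytest.approx([0.0, 30.0])

    def test_base_parallel_to_suture(self):
        contour = [(0, 0), (30, 0), (30, 30), (0, 24)]
        th = math.radians(25)
        u = (math.cos(th), math.sin(th))
        quad, _ = wedge_substitute(contour, u)
        e = (quad[1].x - quad[0].x, quad[1].y - quad[0].y)
        cross = e[0] * u[1] - e[1] * u[0]
        assert cross == pytest.approx(0.0, abs=1e-9)

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            wedge_substitute([(0, 0), (1, 0), (1, 1)], (1, 0))
        with pytest.raises(ValidationError):
            wedge_substitute([(0, 0), (1, 0), (1, 1), (0, 1)], (0, 0))


class TestSmallAngleError:
    @pytest.mark.parametrize(
        "alpha, printed",
        [(0.0, 0.0), (10.0, 0.10), (15.0, 0.35), (20.0, 0.85), (25.0, 1.72),
         (30.0, 3.08)],
    )
    def test_printed_values(self, alpha, printed):
        assert round(small_angle_error(alpha), 2) == pytest.approx(printed)

    def test_closed_form(self):
        for a in np.linspace(0.0, 89.0, 90):
            expected = math.degrees(math.tan(math.radians(a))) - a
            assert small_angle_error(float(a)) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=89.0), st.floats(min_value=0.01, max_value=0.9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing(self, a, step):
        b = min(a + step, 89.9)
        assert small_angle_error(b) > small_angle_error(a) or a == b

    @pytest.mark.parametrize("bad", [-1.0, 90.0, 120.0])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            small_angle_error(bad)
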