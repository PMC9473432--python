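"""CL, EA, SAR, D: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from aortaview.centerline import Centerline3D, Projection2D, RotationAngles
from aortaview.exceptions import DegenerateInputError, ValidationError
from aortaview.geometry import project_to_rpp, rotate_points
from aortaview.metrics import (
    contour_length_2d,
    contour_length_3d,
    enclosed_area,
    evaluate_plane,
    ppp_difference,
    sar,
)
from aortaview.synthetic import AortaTemplateSpec, make_question_mark


class TestContourLength:
    @pytest.mark.parametrize(
        "pts, expected",
        [([(0, 0), (3, 4)], 5.0), ([(0, 0), (1, 0), (1, 1)], 2.0)],
    )
    def test_2d_worked_examples(self, pts, expected):
        assert contour_length_2d(Projection2D(pts)) == pytest.approx(expected)

    def test_3d_345_triangle(self):
        assert contour_length_3d(Centerline3D([(0, 0, 0), (1, 2, 2)])) == 3.0

    def test_random_walk_matches_loop_summed_oracle(self, rng):
        pts = np.cumsum(rng.normal(size=(10_000, 2)), axis=0)
        total = 0.0
        for k in range(len(pts) - 1):  # naive loop oracle
            total += float(np.hypot(*(pts[k + 1] - pts[k])))
        assert contour_length_2d(Projection2D(pts)) == pytest.approx(total, abs=1e-9)

    def test_helix_matches_analytic_length(self):
        t = np.linspace(0, 4 * np.pi, 20_000)
        c = Centerline3D(np.column_stack([np.cos(t), np.sin(t), t]))
        assert contour_length_3d(c) == pytest.approx(
            4 * np.pi * np.sqrt(2.0), rel=1e-3
        )

    def test_fewer_than_two_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            contour_length_2d(Projection2D(np.zeros((1, 2))))


def _random_convex_polygon(rng, n):
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5, 3.0)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)]) + rng.normal(size=2)


class TestEnclosedArea:
    def test_unit_square_both_modes(self):
        sq = Projection2D([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert enclosed_area(sq, "fan_abs") == pytest.approx(1.0)
        assert enclosed_area(sq, "signed_shoelace") == pytest.approx(1.0)

    def test_right_triangle(self):
        tri = Projection2D([(0, 0), (1, 0), (0, 1)])
        assert enclosed_area(tri) == pytest.approx(0.5)

    def test_convex_polygons_fan_equals_shoelace(self, rng):
        for _ in range(200):
            poly = Projection2D(_random_convex_polygon(rng, int(rng.integers(3, 30))))
            fan = enclosed_area(poly, "fan_abs")
            sho = enclosed_area(poly, "signed_shoelace")
            assert fan == pytest.approx(sho, abs=1e-9)

    def test_nonconvex_L_fan_overestimates(self):
        L = Projection2D([(0, 0), (2, 0), (2, 1), (1, 1), (1, 3), (0, 3)])
        fan = enclosed_area(L, "fan_abs")
        sho = enclosed_area(L, "signed_shoelace")
        assert sho == pytest.approx(4.0)
        assert fan >= sho - 1e-12

    def test_fan_dominates_shoelace_on_random_polygons(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(int(rng.integers(4, 20)), 2))
            p = Projection2D(pts)
            if enclosed_area(p, "signed_shoelace") is None:
                continue
            assert (
                enclosed_area(p, "fan_abs")
                >= enclosed_area(p, "signed_shoelace") - 1e-12
            )

    def test_collinear_returns_undefined_not_exception(self):
        line = Projection2D([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert enclosed_area(line) is None

    def test_fewer_than_three_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            enclosed_area(Projection2D([(0, 0), (1, 1)]))

    def test_unknown_mode_rejected(self):
        tri = Projection2D([(0, 0), (1, 0), (0, 1)])
        with pytest.raises(ValidationError):
            enclosed_area(tri, "parallelogram")


class TestSAR:
    def test_symmetric_pair(self):
        c = Centerline3D([(1, 0, 0), (-1, 5, 2)])
        assert sar(c) == pytest.approx(2.0)

    def test_planar_curve_is_zero(self):
        t = np.linspace(0, 1, 50)
        c = Centerline3D(np.column_stack([np.full_like(t, 4.2), t, t**2]))
        assert sar(c) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        pts = rng.normal(size=(1000, 3)) * 40
        xbar = sum(p[0] for p in pts) / len(pts)  # naive oracle
        expected = sum(abs(p[0] - xbar) for p in pts)
        assert sar(Centerline3D(pts)) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_point_order_and_x_shift(self, rng):
        pts = rng.normal(size=(200, 3))
        base = sar(Centerline3D(pts))
        assert sar(Centerline3D(rng.permutation(pts))) == pytest.approx(base, abs=1e-9)
        shifted = pts + np.array([17.3, 0, 0])
        assert sar(Centerline3D(shifted)) == pytest.approx(base, abs=1e-9)

    def test_median_center_never_larger_than_mean_center(self, rng):
        pts = rng.lognormal(size=(100, 3))
        c = Centerline3D(pts)
        assert sar(c, center="median") <= sar(c, center="mean") + 1e-12


class TestPPPDifference:
    @pytest.mark.parametrize(
        "cl3d, cl2d, expected",
        [
            (294.79, 130.12, 164.67),
            (294.79, 260.69, 34.10),
            (294.79, 276.15, 18.64),
            (100.0, 100.0, 0.0),
        ],
    )
    def test_worked_examples(self, cl3d, cl2d, expected):
        assert ppp_difference(cl3d, cl2d) == pytest.approx(expected, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ppp_difference(-1.0, 0.5)

    def test_rounding_level_violation_warns(self):
        with pytest.warns(UserWarning):
            ppp_difference(100.0, 100.0 + 5e-7)

    def test_gross_violation_rejected(self):
        with pytest.raises(ValidationError):
            ppp_difference(100.0, 101.0)


class TestEvaluatePlane:
    def test_planar_curve_identity_angles(self, planar_qmark):
        m = evaluate_plane(planar_qmark)
        assert m.sar == pytest.approx(0.0, abs=1e-9)
        assert m.cl_2d == pytest.approx(m.cl_3d, rel=1e-12)
        assert m.d == pytest.approx(0.0, abs=1e-9)
        assert m.ea is not None and m.ea > 0

    def test_inverse_rotation_recovers_planarity(self, planar_qmark):
        beta, gamma = 0.9, 2.3
        # tilt by Rz(gamma) then Ry(beta); undoing in reverse order
        # (evaluate composes Z after Y) restores exact coplanarity
        pre = rotate_points(
            rotate_points(planar_qmark, RotationAngles(0, 0, gamma)),
            RotationAngles(0, beta, 0),
        )
        undone = rotate_points(pre, RotationAngles(0, -beta, 0))
        m2 = evaluate_plane(undone, RotationAngles(0, 0, -gamma))
        assert m2.sar < 1e-9
        assert m2.cl_2d == pytest.approx(m2.cl_3d, rel=1e-9)

    def test_single_tilt_inverse_recovers_planarity(self, planar_qmark):
        gamma = 1.3
        pre = rotate_points(planar_qmark, RotationAngles(0, 0, gamma))
        m = evaluate_plane(pre, RotationAngles(0, 0, -gamma))
        assert m.sar < 1e-9

    def test_alpha_invariance_at_primary_plane(self, embedded_qmark):
        # Table-3 pattern: rotation about X leaves the YOZ projection's
        # metrics unchanged (beta = gamma = 0)
        c, _ = embedded_qmark
        base = evaluate_plane(c, RotationAngles(0, 0, 0))
        for alpha in (0.35, 1.0, -2.2, 5.9):
            m = evaluate_plane(c, RotationAngles(alpha, 0, 0))
            assert m.cl_2d == pytest.approx(base.cl_2d, abs=1e-9)
            assert m.sar == pytest.approx(base.sar, abs=1e-9)
            assert m.ea == pytest.approx(base.ea, abs=1e-6)

    def test_metric_correlations_across_random_planes(self, rng):
        # across random rotations of a noisy near-planar curve, CL and EA
        # move together and both move against SAR
        c = make_question_mark(
            AortaTemplateSpec(noise_sd=0.5, embed_angles=(0, 0, 0), seed=3)
        )
        cls, eas, sars = [], [], []
        for _ in range(200):
            m = evaluate_plane(c, RotationAngles(0, *rng.uniform(0, 2 * np.pi, 2)))
            cls.append(m.cl_2d)
            eas.append(0.0 if m.ea is None else m.ea)
            sars.append(m.sar)
        assert spearmanr(cls, eas).statistic > 0
        assert spearmanr(cls, sars).statistic < 0
        assert spearmanr(eas, sars).statistic < 0

    def test_projection_shortening_randomized(self, rng):
        c = make_question_mark(
            AortaTemplateSpec(out_of_plane_amp=4.0, embed_angles=(0.5, 1.0, 1.5))
        )
        for _ in range(500):
            m = evaluate_plane(c, RotationAngles(*rng.uniform(0, 2 * np.pi, 3)))
            assert m.cl_2d <= m.cl_3d + 1e-9
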