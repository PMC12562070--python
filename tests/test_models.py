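"""Polynomial model fits, circle fitting and circle-fit lordosis."""

import numpy as np
import pytest

import lumbarseg as ls
from lumbarseg.markers import LUMBAR_LABELS, MODEL_REQUIRED_LABELS
from lumbarseg.models import CircleFitError, NonMonotoneSpineError, is_collinear

from conftest import circumcircle, triangle_area


def capture_from_points(points, phase="static_1"):
    pts = {lb: np.asarray(p, dtype=float) for lb, p in points.items()}
    return ls.CaptureInstant("P01", "STA", phase, 0, pts)


def capture_from_pose(arc_deg, geometry, thor=0.0, pelv=0.0):
    """Single-frame capture through the real projection path."""
    pose = ls.SpinePoseParams(arc_deg, thor, pelv, geometry.lumbar_chain_mm)
    markers = {lb: p[None, :] for lb, p in
               ls.build_spine_chain(pose, geometry).items()}
    trial = ls.TrialRecording("P01", "STA", 120.0, markers)
    pf = ls.pelvis_frame(trial)
    pts = ls.project_capture(trial, pf, 0, MODEL_REQUIRED_LABELS)
    return ls.CaptureInstant("P01", "STA", "static_1", 0, pts)


class TestFitModel:
    def test_two_point_model_is_exact_line(self):
        cap = capture_from_points({"L1": (100.0, 5.0), "L5": (0.0, -3.0)})
        fit = ls.fit_model(cap, ls.MODEL_SPECS[1])
        assert fit.eval_v[0] == pytest.approx(5.0, abs=1e-12)
        assert fit.eval_v[-1] == pytest.approx(-3.0, abs=1e-12)
        assert fit.eval_v[2] == pytest.approx(1.0, abs=1e-12)  # midpoint

    def test_three_point_quadratic_recovers_parabola(self):
        u = np.array([300.0, 180.0, 60.0])
        cap = capture_from_points({lb: (ui, ui ** 2 / 1000.0)
                                   for lb, ui in zip(("L1", "L3", "L5"), u)})
        fit = ls.fit_model(cap, ls.MODEL_SPECS[3])
        assert np.abs(fit.coefficients - [0.0, 0.0, 1e-3]).max() < 1e-10

    def test_exact_interpolation_at_degree_plus_one_points(self, geometry):
        cap = capture_from_pose(-37.0, geometry)
        for mid in (1, 2, 3):
            spec = ls.MODEL_SPECS[mid]
            fit = ls.fit_model(cap, spec)
            u = np.array([cap.points[lb][0] for lb in spec.marker_labels])
            v = np.array([cap.points[lb][1] for lb in spec.marker_labels])
            from numpy.polynomial import polynomial as P
            assert np.abs(P.polyval(u, fit.coefficients) - v).max() < 1e-10

    def test_model4_on_circle_arc_within_dense_grid_bound(self, geometry):
        cap = capture_from_pose(-50.0, geometry)
        u_range = (cap.points["L1"][0], cap.points["L5"][0])
        fit = ls.fit_model(cap, ls.MODEL_SPECS[4], u_range=u_range)
        center, radius = circumcircle(cap.points["L1"], cap.points["L3"],
                                      cap.points["L5"])
        u = np.linspace(min(u_range), max(u_range), 2000)
        # pick the circle branch the markers actually lie on
        side = np.sign(np.mean([cap.points[lb][1] for lb in LUMBAR_LABELS])
                       - center[1])
        v_arc = center[1] + side * np.sqrt(radius ** 2 - (u - center[0]) ** 2)
        dense_coeffs = np.polynomial.polynomial.polyfit(u, v_arc, 2)
        dense_resid = np.abs(
            np.polynomial.polynomial.polyval(u, dense_coeffs) - v_arc).max()
        fit_resid = np.abs(
            np.polynomial.polynomial.polyval(u, fit.coefficients) - v_arc).max()
        assert fit_resid <= 2.0 * dense_resid

    def test_shared_evaluation_range_applies(self, geometry):
        cap = capture_from_pose(-37.0, geometry)
        u_range = (cap.points["L1"][0], cap.points["L5"][0])
        fit2 = ls.fit_model(cap, ls.MODEL_SPECS[2], u_range=u_range)
        assert fit2.eval_u[0] == pytest.approx(u_range[0])
        assert fit2.eval_u[-1] == pytest.approx(u_range[1])

    def test_non_monotone_u_rejected(self):
        cap = capture_from_points({"L1": (100.0, 0.0), "L3": (120.0, 1.0),
                                   "L5": (80.0, 2.0)})
        with pytest.raises(NonMonotoneSpineError):
            ls.fit_model(cap, ls.MODEL_SPECS[3])

    def test_duplicate_u_rejected(self):
        cap = capture_from_points({"L1": (100.0, 0.0), "L5": (100.0, 2.0)})
        with pytest.raises(NonMonotoneSpineError):
            ls.fit_model(cap, ls.MODEL_SPECS[1])


class TestFitCircle:
    def test_unit_circumcircle(self):
        center, radius = ls.fit_circle(np.array([[0, 1], [1, 0], [0, -1.0]]))
        assert np.abs(center).max() < 1e-12
        assert radius == pytest.approx(1.0, abs=1e-12)

    def test_random_three_point_sets_match_closed_form(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            pts = rng.uniform(-100, 100, size=(3, 2))
            area = triangle_area(pts)
            if area < 10.0:
                continue
            c_ref, r_ref = circumcircle(*pts)
            c, r = ls.fit_circle(pts)
            assert np.abs(c - c_ref).max() < 1e-9 * max(1.0, r_ref)
            assert abs(r - r_ref) < 1e-9 * max(1.0, r_ref)
            checked += 1

    def test_five_points_on_circle_recovered(self):
        angles = np.deg2rad([10, 40, 80, 150, 220.0])
        pts = np.column_stack([3 + 50 * np.cos(angles), 7 + 50 * np.sin(angles)])
        center, radius = ls.fit_circle(pts)
        assert np.abs(center - [3, 7]).max() < 1e-9
        assert radius == pytest.approx(50.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(CircleFitError):
            ls.fit_circle(pts)

    def test_collinearity_predicate(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert is_collinear(line, tol_mm=1e-9)
        bent = line.copy()
        bent[2, 1] += 0.5
        assert not is_collinear(bent, tol_mm=1e-3)


class TestLordosis:
    @pytest.mark.parametrize("arc", [-55.0, -37.0, -12.0, 15.0, 40.0, 55.0])
    def test_recovers_commanded_arc_with_sign(self, geometry, arc):
        cap = capture_from_pose(arc, geometry)
        res = ls.lordosis_angle(cap)
        assert res.angle_deg == pytest.approx(arc, abs=1e-6)

    def test_sta_against_own_reference_is_zero(self, geometry):
        cap = capture_from_pose(ls.STA_ARC_DEG, geometry)
        res = ls.lordosis_angle(cap)
        res_rel = ls.lordosis_angle(cap, sta_reference_deg=res.angle_deg)
        assert res_rel.relative_deg == pytest.approx(0.0, abs=1e-12)

    def test_pelvis_rotation_leaves_lordosis(self, geometry):
        a = ls.lordosis_angle(capture_from_pose(-30.0, geometry, pelv=0.0))
        b = ls.lordosis_angle(capture_from_pose(-30.0, geometry, pelv=40.0))
        assert a.angle_deg == pytest.approx(b.angle_deg, abs=1e-9)

    def test_monotone_in_commanded_arc(self, geometry):
        arcs = np.linspace(-55.0, 55.0, 23)
        measured = [ls.lordosis_angle(capture_from_pose(a, geometry)).angle_deg
                    for a in arcs]
        assert np.all(np.diff(measured) > 0)

    def test_straight_spine_path(self):
        pts = {lb: (u, 0.3 * u) for lb, u in
               zip(LUMBAR_LABELS, (300.0, 240.0, 180.0, 120.0, 60.0))}
        res = ls.lordosis_angle(capture_from_points(pts))
        assert res.straight
        assert res.angle_deg == 0.0

    def test_exact_quadratic_makes_models_3_and_4_identical(self):
        u = np.array([300.0, 240.0, 180.0, 120.0, 60.0])
        v = 2e-4 * u ** 2 - 0.1 * u + 5.0
        cap = capture_from_points(dict(zip(LUMBAR_LABELS, zip(u, v))))
        u_range = (u[0], u[-1])
        f3 = ls.fit_model(cap, ls.MODEL_SPECS[3], u_range=u_range)
        f4 = ls.fit_model(cap, ls.MODEL_SPECS[4], u_range=u_range)
        r = ls.pearson_pair(f3, f4, cap).r
        assert abs(r - 1.0) < 1e-12
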