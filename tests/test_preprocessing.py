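"""Filtering, gap filling, lumbar reconstruction, pelvis frame, projection."""

import numpy as np
import pytest
from scipy import signal

import lumbarseg as ls
from lumbarseg.markers import LUMBAR_LABELS
from lumbarseg.preprocessing import DegeneratePelvisError, GapFillError

from conftest import RATE, circumcircle, make_trial, rotation_about


def analytic_gain(freq_hz, cutoff=5.0, order=4, rate=RATE):
    """|H|^2 of the designed digital Butterworth (zero-phase = squared)."""
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=rate)
    return float(np.abs(h[0]) ** 2)


class TestLowpassFilter:
    def test_constant_trajectory_unchanged(self, sta_trial_clean):
        out = ls.lowpass_filter(sta_trial_clean)
        lb = "L3"
        assert np.abs(out.markers[lb] - sta_trial_clean.markers[lb]).max() < 1e-9

    @pytest.mark.parametrize("freq", [0.1, 5.0])
    def test_sinusoid_gain_matches_analytic_response(self, freq):
        n = int(30 * RATE)
        t = np.arange(n) / RATE
        wave = 10.0 * np.sin(2 * np.pi * freq * t)
        markers = {"L3": np.column_stack([wave, np.zeros(n), np.zeros(n)])}
        trial = ls.TrialRecording("P", "STA", RATE, markers)
        out = ls.lowpass_filter(trial).markers["L3"][:, 0]
        mid = slice(n // 4, 3 * n // 4)  # avoid edge transients
        measured = np.ptp(out[mid]) / np.ptp(wave[mid])
        assert measured == pytest.approx(analytic_gain(freq), rel=0.01)

    def test_rejects_cutoff_at_nyquist(self, sta_trial_clean):
        with pytest.raises(ValueError, match="Nyquist"):
            ls.lowpass_filter(sta_trial_clean, cutoff_hz=60.0)

    def test_rejects_missing_samples(self):
        trial = make_trial("STA", noise_sd=1.0, gap_rate=0.5, seed=1)
        with pytest.raises(GapFillError):
            ls.lowpass_filter(trial)


class TestFillGaps:
    def test_linear_motion_gap_filled_exactly(self):
        n = 200
        t = np.arange(n, dtype=float)
        line = np.column_stack([3 * t + 1, -2 * t, 0.5 * t + 7])
        arr = line.copy()
        arr[50:55] = np.nan
        trial = ls.TrialRecording("P", "STA", RATE, {"C7": arr})
        out, report = ls.fill_gaps(trial)
        assert np.abs(out.markers["C7"] - line).max() < 1e-6
        assert [e.method for e in report.entries] == ["spline"]

    def test_no_gaps_is_identity(self, sta_trial_clean):
        out, report = ls.fill_gaps(sta_trial_clean)
        assert report.entries == []
        assert np.array_equal(out.markers["L3"], sta_trial_clean.markers["L3"])

    def test_long_gap_without_donors_reported_not_filled(self):
        n = 300
        arr = np.random.default_rng(0).normal(size=(n, 3))
        arr[100:160] = np.nan  # 60 frames > default max_gap, marker has no donors
        trial = ls.TrialRecording("P", "STA", RATE, {"C7": arr})
        out, report = ls.fill_gaps(trial)
        assert out.missing_mask("C7").sum() == 60
        assert [e.method for e in report.unfilled] == ["unfilled"]

    def test_boundary_gap_without_donors_is_error(self):
        arr = np.zeros((100, 3))
        arr[:10] = np.nan
        trial = ls.TrialRecording("P", "STA", RATE, {"C7": arr})
        with pytest.raises(GapFillError, match="C7"):
            ls.fill_gaps(trial)


class TestReconstructLumbar:
    @staticmethod
    def _rigid_motion_trial():
        """Constant pose under a time-varying global rigid transform."""
        base = make_trial("STA")
        n = base.frame_count
        angles = np.linspace(0, 40, n)
        R = np.stack([rotation_about([0, 1, 0], a) for a in angles])
        t = np.column_stack([np.linspace(0, 200, n), np.zeros(n),
                             np.linspace(0, 50, n)])
        return base.transformed(R, t)

    def test_rigid_motion_reconstruction_exact(self):
        trial = self._rigid_motion_trial()
        truth = trial.markers["L3"].copy()
        trial.markers["L3"][100:150] = np.nan
        out = ls.reconstruct_lumbar(trial, "L3")
        assert np.abs(out.markers["L3"] - truth).max() < 1e-6

    def test_donors_missing_too_is_error(self):
        trial = self._rigid_motion_trial()
        trial.markers["L3"][:] = np.nan
        trial.markers["LL2"][:] = np.nan
        with pytest.raises(GapFillError, match="calibration"):
            ls.reconstruct_lumbar(trial, "L3")

    def test_noisy_reconstruction_rmse_bounded(self):
        sd = 2.0
        clean = self._rigid_motion_trial()
        truth = clean.markers["L3"].copy()
        rng = np.random.default_rng(42)
        noisy = clean.copy()
        for lb in noisy.markers:
            noisy.markers[lb] = noisy.markers[lb] + rng.normal(0, sd, (clean.frame_count, 3))
        noisy.markers["L3"][100:150] = np.nan
        out = ls.reconstruct_lumbar(noisy, "L3")
        err = out.markers["L3"][100:150] - truth[100:150]
        rmse = np.sqrt((err ** 2).sum(axis=1).mean())
        assert rmse <= 2 * sd

    def test_non_lumbar_target_rejected(self):
        with pytest.raises(ValueError):
            ls.reconstruct_lumbar(self._rigid_motion_trial(), "C7")


class TestPelvisFrame:
    def test_axis_aligned_pose_equals_world_axes(self, sta_trial_clean):
        pf = ls.pelvis_frame(sta_trial_clean)
        assert np.abs(pf.ml - [0, 1, 0]).max() < 1e-10
        assert np.abs(pf.ap - [1, 0, 0]).max() < 1e-10
        assert np.abs(pf.longitudinal - [0, 0, 1]).max() < 1e-10

    def test_rotation_about_ml_rotates_ap_and_longitudinal(self, sta_trial_clean):
        R = rotation_about([0, 1, 0], 30.0)
        pf0 = ls.pelvis_frame(sta_trial_clean)
        pf1 = ls.pelvis_frame(sta_trial_clean.transformed(R, np.zeros(3)))
        assert np.abs(pf1.ml - pf0.ml).max() < 1e-9  # ML is the rotation axis
        assert np.abs(pf1.ap - pf0.ap @ R.T).max() < 1e-9
        assert np.abs(pf1.longitudinal - pf0.longitudinal @ R.T).max() < 1e-9

    def test_orthonormal_and_right_handed(self):
        trial = make_trial("F", noise_sd=2.0, seed=8)
        filled, _ = ls.fill_gaps(trial)
        pf = ls.pelvis_frame(filled)
        for a, b in [(pf.ml, pf.ap), (pf.ml, pf.longitudinal), (pf.ap, pf.longitudinal)]:
            assert np.abs(np.sum(a * b, axis=1)).max() < 1e-10
        M = np.stack([pf.ap, pf.ml, pf.longitudinal], axis=2)
        # det +1 whatever the pose (handedness enforced by construction)
        assert np.abs(np.abs(np.linalg.det(M)) - 1).max() < 1e-10
        assert (np.cross(pf.ap, pf.ml) * pf.longitudinal).sum(axis=1).min() > 0.999

    def test_mirrored_markers_keep_cranial_longitudinal(self, sta_trial_clean):
        mirrored = sta_trial_clean.copy()
        for lb in mirrored.markers:  # reflect left-right
            mirrored.markers[lb][:, 1] *= -1
        swaps = {"LPSIS": "RPSIS", "RPSIS": "LPSIS", "LASIS": "RASIS",
                 "RASIS": "LASIS", "LTIP": "RTIP", "RTIP": "LTIP"}
        mirrored.markers = {swaps.get(lb, lb): arr
                            for lb, arr in mirrored.markers.items()}
        pf = ls.pelvis_frame(mirrored)
        assert pf.longitudinal[0] @ np.array([0, 0, 1]) > 0.999

    def test_degenerate_pelvis_rejected(self):
        arr = np.ones((100, 3))
        markers = {lb: arr.copy() for lb in ("LPSIS", "RPSIS", "LASIS", "RASIS")}
        trial = ls.TrialRecording("P", "STA", RATE, markers)
        with pytest.raises(DegeneratePelvisError):
            ls.pelvis_frame(trial)

    def test_tip_definition_available(self, sta_trial_clean):
        pf = ls.pelvis_frame(sta_trial_clean, ml_definition="tip")
        assert np.abs(pf.ml - [0, 1, 0]).max() < 1e-10


class TestProjection:
    def test_in_plane_distances_preserved(self, sta_trial_clean):
        pf = ls.pelvis_frame(sta_trial_clean)
        a = ls.project_series(sta_trial_clean, pf, "L1")
        b = ls.project_series(sta_trial_clean, pf, "L5")
        d2 = np.linalg.norm(a - b, axis=1)
        d3 = np.linalg.norm(sta_trial_clean.markers["L1"]
                            - sta_trial_clean.markers["L5"], axis=1)
        assert np.abs(d2 - d3).max() < 1e-9  # midline markers are in-plane

    def test_mirrored_pair_projects_identically(self, sta_trial_clean):
        pf = ls.pelvis_frame(sta_trial_clean)
        left = ls.project_series(sta_trial_clean, pf, "LL2")
        right = ls.project_series(sta_trial_clean, pf, "RL2")
        assert np.abs(left - right).max() < 1e-9

    def test_projected_lumbar_points_on_commanded_circle(self, fe_trial_clean):
        pf = ls.pelvis_frame(fe_trial_clean)
        frame = 600
        pts = ls.project_capture(fe_trial_clean, pf, frame, LUMBAR_LABELS)
        center, radius = circumcircle(pts["L1"], pts["L3"], pts["L5"])
        for lb in LUMBAR_LABELS:
            assert np.linalg.norm(pts[lb] - center) == pytest.approx(radius, abs=1e-6)

    def test_missing_sample_raises(self, sta_trial_clean):
        trial = sta_trial_clean.copy()
        trial.markers["L3"][10] = np.nan
        pf = ls.pelvis_frame(trial)
        with pytest.raises(ls.TrialError, match="L3"):
            ls.project_capture(trial, pf, 10, LUMBAR_LABELS)

    def test_global_rigid_transform_leaves_sagittal_coords(self, fe_trial_clean):
        R = rotation_about([0.3, 1.0, -0.2], 25.0)
        t = np.array([120.0, -40.0, 300.0])
        moved = fe_trial_clean.transformed(R, t)
        pf0 = ls.pelvis_frame(fe_trial_clean)
        pf1 = ls.pelvis_frame(moved)
        for lb in ("C7", "L1", "L3", "S1"):
            a = ls.project_series(fe_trial_clean, pf0, lb)
            b = ls.project_series(moved, pf1, lb)
            assert np.abs(a - b).max() < 1e-6
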