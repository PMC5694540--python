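"""Filtering, stroke segmentation, frame transform and kinematic variables."""

import numpy as np
import pytest

import hoverfeed as hf
from hoverfeed import kinematics as kin
from hoverfeed.datatypes import LANDMARK_NAMES
from hoverfeed.simulate import KinematicSimParams


def _reflect_sagittal(ls):
    """Mirror a landmark set through the x-z plane, swapping left/right."""
    swap = {
        "l_shoulder": "r_shoulder", "r_shoulder": "l_shoulder",
        "l_wingtip": "r_wingtip", "r_wingtip": "l_wingtip",
        "l_p5": "r_p5", "r_p5": "l_p5",
        "head": "head", "tail": "tail",
    }
    pos = {}
    for name in LANDMARK_NAMES:
        src = ls.positions[swap[name]].copy()
        src[:, 1] = -src[:, 1]
        pos[name] = src
    out = ls.copy_with(pos)
    out.meta = dict(ls.meta)
    out.meta["mode"] = {"left": "right", "right": "left", "hover": "hover"}[ls.meta["mode"]]
    return out


class TestFiltering:
    def test_constant_trajectory_unchanged(self, symmetric_hover_landmarks):
        ls = symmetric_hover_landmarks
        pos = {n: np.full_like(ls[n], 0.123) for n in LANDMARK_NAMES}
        out = kin.filter_trajectories(ls.copy_with(pos), 39.0)
        np.testing.assert_allclose(out["head"], 0.123, atol=1e-9)

    def test_head_cutoff_attenuates_200hz_keeps_39hz(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        low = np.sin(2 * np.pi * 39.0 * t)
        high = 0.5 * np.sin(2 * np.pi * 200.0 * t)
        pos = {n: np.zeros((len(t), 3)) for n in LANDMARK_NAMES}
        pos["head"][:, 0] = low + high
        ls = hf.LandmarkSet(t, pos, fs)
        out = kin.filter_trajectories(ls, 39.0)["head"][:, 0]
        mid = slice(500, 3500)  # away from edge transients

        def amp(sig, f):
            return 2 * np.abs(np.exp(-2j * np.pi * f * t[mid]) @ sig[mid]) / len(sig[mid])

        assert amp(out, 200.0) / 0.5 < 10 ** (-40 / 20)   # > 40 dB down
        assert amp(out, 39.0) == pytest.approx(1.0, abs=0.05)

    def test_zero_phase_no_lag(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        sig = np.sin(2 * np.pi * 30.0 * t)
        pos = {n: np.zeros((len(t), 3)) for n in LANDMARK_NAMES}
        pos["head"][:, 0] = sig
        out = kin.filter_trajectories(hf.LandmarkSet(t, pos, fs), 39.0)["head"][:, 0]
        xc = np.correlate(out[500:3500], sig[500:3500], "full")
        assert np.argmax(xc) == len(sig[500:3500]) - 1  # peak at zero lag

    def test_filtering_near_idempotent_in_passband(self, symmetric_hover_landmarks):
        once = kin.filter_trajectories(symmetric_hover_landmarks, 39.0)
        twice = kin.filter_trajectories(once, 39.0)
        rel = once["l_wingtip"] - once["l_shoulder"]
        rel2 = twice["l_wingtip"] - twice["l_shoulder"]
        assert np.max(np.abs(rel - rel2)) < 0.02 * np.max(np.abs(rel))

    def test_cutoff_beyond_nyquist_rejected(self, symmetric_hover_landmarks):
        with pytest.raises(ValueError):
            kin.filter_trajectories(symmetric_hover_landmarks, 70.0)  # 8f = 560 > 500


class TestSegmentation:
    def test_frequency_recovered_within_half_hertz(self, symmetric_hover_landmarks):
        seg = kin.segment_strokes(kin.filter_trajectories(symmetric_hover_landmarks, 39.0))
        assert seg.wingbeat_freq_hz == pytest.approx(39.0, abs=0.5)

    def test_extrema_at_waveform_extrema(self, symmetric_hover_landmarks):
        # the generator pronates at integer multiples of the period
        seg = kin.segment_strokes(kin.filter_trajectories(symmetric_hover_landmarks, 39.0))
        period = 1.0 / 39.0
        offsets = np.mod(seg.pronation_s["left"] + period / 2, period) - period / 2
        assert np.max(np.abs(offsets)) < 1.5e-3
        sup_offsets = np.mod(seg.supination_s["left"] - 0.48 * period + period / 2, period) - period / 2
        assert np.max(np.abs(sup_offsets)) < 1.5e-3

    def test_extrema_robust_to_positional_noise(self):
        quiet = hf.generate_landmark_trajectories(KinematicSimParams(noise_sd_m=0.0, seed=1))
        noisy = hf.generate_landmark_trajectories(KinematicSimParams(noise_sd_m=0.0005, seed=1))
        sq = kin.segment_strokes(kin.filter_trajectories(quiet, 39.0))
        sn = kin.segment_strokes(kin.filter_trajectories(noisy, 39.0))
        n = min(len(sq.pronation_s["left"]), len(sn.pronation_s["left"]))
        assert np.max(np.abs(sq.pronation_s["left"][:n] - sn.pronation_s["left"][:n])) < 1e-3

    def test_fewer_than_three_cycles_rejected(self):
        ls = hf.generate_landmark_trajectories(KinematicSimParams(n_wingbeats=2, noise_sd_m=0))
        with pytest.raises(ValueError):
            kin.segment_strokes(kin.filter_trajectories(ls, 39.0))


class TestTransform:
    def test_translation_invariance(self, symmetric_hover_landmarks):
        ls = symmetric_hover_landmarks
        work = kin.filter_trajectories(ls, 39.0)
        seg = kin.segment_strokes(work)
        base, _ = kin.transform_frame(work, seg)
        shifted = work.copy_with({n: work[n] + np.array([0.3, -0.2, 0.5]) for n in LANDMARK_NAMES})
        moved, _ = kin.transform_frame(shifted, kin.segment_strokes(shifted))
        for n in LANDMARK_NAMES:
            np.testing.assert_allclose(moved[n], base[n], atol=1e-9)

    def test_hovering_transform_keeps_head_at_origin(self, symmetric_hover_landmarks):
        work = kin.filter_trajectories(symmetric_hover_landmarks, 39.0)
        out, infos = kin.transform_frame(work, kin.segment_strokes(work))
        np.testing.assert_allclose(out["head"], 0.0, atol=1e-12)
        assert all(abs(i["yaw_deg"]) < 1.0 for i in infos)

    def test_travel_yaw_recovered(self, left_summary):
        assert left_summary.psi_deg == pytest.approx(21.9, abs=1.0)


class TestVariables:
    @pytest.mark.parametrize(
        "left, right, expected", [(4.0, -4.0, 4.0), (2.5, 2.5, 0.0), (-7.4, 7.4, -7.4)]
    )
    def test_wba(self, left, right, expected):
        assert kin.compute_wba(left, right) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "wba, chi, expected", [(4.0, 3.5, 7.5), (-7.4, -1.3, 8.7), (5.0, -5.0, 0.0)]
    )
    def test_rwba(self, wba, chi, expected):
        assert kin.compute_rwba(wba, chi) == pytest.approx(expected)

    def test_body_angles_horizontal_and_vertical_axes(self):
        head = np.array([[0.05, 0.0, 0.0]])
        tail = np.array([[0.0, 0.0, 0.0]])
        l_sh = np.array([[0.02, 0.01, 0.0]])
        r_sh = np.array([[0.02, -0.01, 0.0]])
        chi_xz, chi_yz = kin.compute_body_angles(head, tail, l_sh, r_sh)
        assert chi_xz[0] == pytest.approx(0.0, abs=1e-9)   # horizontal body axis
        assert chi_yz[0] == pytest.approx(0.0, abs=1e-9)   # vertical dorsoventral axis

    def test_body_angles_reject_coincident_head_tail(self):
        p = np.zeros((1, 3))
        with pytest.raises(ValueError):
            kin.compute_body_angles(p, p, p + [0, 1, 0], p - [0, 1, 0])

    def test_travel_angle_conventions(self):
        # bird facing 21.9 deg into leftward travel
        yaw = np.radians(21.9)
        div = np.array([-np.sin(yaw), np.cos(yaw), 0.0])
        assert kin.compute_travel_angle(div, "left") == pytest.approx(21.9)
        assert kin.compute_travel_angle(np.array([0.0, 1.0, 0.0]), "left") == pytest.approx(0.0)
        # yawed 10.3 deg away from rightward travel
        yaw = np.radians(10.3)
        div = np.array([-np.sin(yaw), np.cos(yaw), 0.0])
        assert kin.compute_travel_angle(div, "right") == pytest.approx(-10.3)
        assert kin.compute_travel_angle(div, None) is None

    @pytest.mark.parametrize("tilt, expected", [(0.0, 0.0), (90.0, 90.0), (45.0, 45.0)])
    def test_geometric_alpha_analytic_planes(self, tilt, expected):
        a = np.radians(tilt)
        sh = np.array([[0.0, 0.0, 0.0]])
        tip = np.array([[0.0, 0.05, 0.0]])                      # span along y
        p5 = np.array([[0.01 * np.cos(a), 0.03, -0.01 * np.sin(a)]])
        assert kin.compute_geometric_alpha(sh, tip, p5)[0] == pytest.approx(expected, abs=1e-6)

    def test_collinear_frames_interpolated(self):
        sh = np.zeros((3, 3))
        tip = np.tile([0.0, 0.05, 0.0], (3, 1))
        p5 = np.array([[0.01, 0.03, 0.0], [0.0, 0.03, 0.0], [0.01, 0.03, 0.0]])
        alpha = kin.compute_geometric_alpha(sh, tip, p5)
        assert alpha[1] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "head_x, expected",
        [(0.0, 0.0),          # bill tip exactly at the mouth plane
         (0.02, 100.0),       # whole culmen inside
         (0.00496, 24.8)],    # study-scale insertion
    )
    def test_bill_insertion(self, head_x, expected):
        head = np.array([[head_x - 0.02, 0.0, 0.0]])
        out = kin.compute_bill_insertion(
            head, np.array([[1.0, 0.0, 0.0]]), np.zeros(3), np.array([1.0, 0.0, 0.0]), 0.02
        )
        assert out[0] == pytest.approx(expected, abs=1e-6)


class TestSummary:
    def test_rwba_identity_holds_on_every_summary(self, left_summary):
        s = left_summary
        per = s.per_wingbeat
        np.testing.assert_allclose(
            per["rwba_ds"], np.abs(per["wba_ds"] + per["chi_yz_ds"]), atol=1e-9
        )
        assert s.rwba_ds_deg >= 0.0 and s.rwba_us_deg >= 0.0

    def test_aggregation_orders_agree_away_from_zero(self, left_summary, left_tracking_landmarks):
        alt = hf.summarize_trial(left_tracking_landmarks, rwba_aggregation="abs_of_mean")
        assert alt.rwba_ds_deg == pytest.approx(left_summary.rwba_ds_deg, abs=0.2)

    def test_mirror_symmetry_negates_lateral_variables(self, left_tracking_landmarks, left_summary):
        mirrored = hf.summarize_trial(_reflect_sagittal(left_tracking_landmarks))
        assert mirrored.wba_ds_deg == pytest.approx(-left_summary.wba_ds_deg, abs=1e-6)
        assert mirrored.chi_yz_ds_deg == pytest.approx(-left_summary.chi_yz_ds_deg, abs=1e-6)
        assert mirrored.psi_deg == pytest.approx(left_summary.psi_deg, abs=1e-6)
        assert mirrored.chi_xz_ds_deg == pytest.approx(left_summary.chi_xz_ds_deg, abs=1e-6)

    def test_hover_reports_absent_travel_angle(self, symmetric_hover_landmarks):
        assert hf.summarize_trial(symmetric_hover_landmarks).psi_deg is None

    def test_single_wingbeat_record_rejected(self):
        ls = hf.generate_landmark_trajectories(KinematicSimParams(n_wingbeats=1, noise_sd_m=0))
        with pytest.raises(ValueError):
            hf.summarize_trial(ls)

    def test_stroke_amplitude_recovered(self, left_summary):
        assert left_summary.stroke_amplitude_deg == pytest.approx(150.0, abs=2.0)


class TestAverageCycle:
    def test_cycle_matches_direct_construction(self, left_tracking_landmarks):
        p = hf.preset_params("left")
        measured = hf.average_cycle(left_tracking_landmarks)
        direct = hf.synthetic_wingbeat_cycle(p)
        assert measured.wingbeat_freq_hz == pytest.approx(41.0, abs=0.5)
        np.testing.assert_allclose(
            measured.elevation_deg["left"], direct.elevation_deg["left"], atol=1.5
        )
        np.testing.assert_allclose(measured.v_body, direct.v_body, atol=0.01)
        assert measured.psi_deg == pytest.approx(21.9, abs=1.0)
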