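import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from uplimb.datamodel import CHANNELS, ValidationError
from uplimb.kinect import kinematics_kinect
from uplimb.synthetic import (
    BodyModel,
    SensorErrorModel,
    corrupt,
    default_task_profiles,
    forward_kinematics,
    generate_corpus,
    generate_truth,
    minimum_jerk,
)
from uplimb.uwa import kinematics_uwa


class TestMinimumJerk:
    def test_boundary_conditions(self):
        tau = np.linspace(0, 1, 1001)
        s = minimum_jerk(tau)
        assert s[0] == 0.0 and s[-1] == 1.0
        v = np.diff(s)
        assert abs(v[0]) < 1e-5 and abs(v[-1]) < 1e-5  # zero boundary velocity
        assert np.all(np.diff(s) >= -1e-12)  # monotone

    def test_midpoint_is_half(self):
        # 10/8 - 15/16 + 6/32 = 1/2
        assert minimum_jerk(0.5) == pytest.approx(0.5)


class TestGenerateTruth:
    def test_endpoint_reached_exactly(self, profiles):
        p = profiles["t1_contralateral_shoulder"]
        wf = generate_truth(p)
        for ci, ch in enumerate(CHANNELS):
            assert wf.values[-1, ci] == pytest.approx(p.end[ch], abs=1e-9)
            assert wf.values[0, ci] == pytest.approx(p.start[ch], abs=1e-9)

    def test_via_point_channel_reaches_extremum(self, profiles):
        p = profiles["t1_contralateral_shoulder"]
        wf = generate_truth(p)
        aa = wf.channel("AA")
        # the via extremum falls between samples; agreement to sub-millidegree
        assert aa.min() == pytest.approx(p.via["AA"], abs=1e-3)
        assert np.ptp(aa) == pytest.approx(abs(p.via["AA"] - p.start["AA"]),
                                           abs=1e-3)

    def test_seeded_determinism(self, profiles):
        p = profiles["t3_comb_hair"]
        a = generate_truth(p, seed=123)
        b = generate_truth(p, seed=123)
        np.testing.assert_array_equal(a.values, b.values)


class TestForwardKinematics:
    def test_central_round_trip_phi_and_gamma(self, profiles, body):
        """The generator is the exact inverse of both angle models."""
        for task in ("t1_contralateral_shoulder", "t3_comb_hair"):
            truth = generate_truth(profiles[task], seed=9)
            mocap, kinect, static = forward_kinematics(truth, body,
                                                       start_offset_s=0.3)
            spline = CubicSpline(truth.meta["times"], truth.values, axis=0)

            k_phi = kinematics_kinect(kinect)
            expected = spline(kinect.times + 0.3)
            np.testing.assert_allclose(k_phi.values, expected, atol=1e-6)

            k_gamma = kinematics_uwa(mocap, static=static)
            np.testing.assert_allclose(k_gamma.values, spline(mocap.times),
                                       atol=1e-6)

    def test_flexed_elbow_places_wrist_analytically(self, body):
        # neutral shoulder, elbow at 90 deg: forearm along the anterior axis
        angles = np.tile([0.0, 0.0, 0.0, 90.0], (300, 1))
        from uplimb.synthetic import _landmark_trajectories

        pos = _landmark_trajectories(angles, body)
        ER, WR = pos["ER"][0], pos["WR"][0]
        np.testing.assert_allclose(
            WR, ER + body.forearm_len * np.array([0.0, 0.0, -1.0]), atol=1e-9)

    def test_rates_and_offset(self, profiles, body):
        truth = generate_truth(profiles["t2_hand_to_mouth"], seed=2)
        mocap, kinect, _ = forward_kinematics(truth, body, start_offset_s=0.5)
        assert mocap.rate_hz == 100.0 and kinect.rate_hz == 30.0
        assert kinect.times[0] == 0.0
        assert kinect.meta["start_offset_s"] == 0.5

    def test_out_of_range_angles_rejected(self, body):
        bad = generate_truth(default_task_profiles()["t3_comb_hair"])
        bad.values[:, 0] = 200.0
        with pytest.raises(ValidationError):
            forward_kinematics(bad, body)


class TestCorrupt:
    def _clean_stream(self, profiles, body):
        truth = generate_truth(profiles["t3_comb_hair"], seed=4)
        _, kinect, _ = forward_kinematics(truth, body)
        return kinect

    def test_zero_gain_is_exact_identity(self, profiles, body):
        kinect = self._clean_stream(profiles, body)
        out = corrupt(kinect, SensorErrorModel(gain=0.0), seed=1)
        for n in kinect.positions:
            np.testing.assert_array_equal(out.positions[n],
                                          kinect.positions[n])

    def test_jitter_sample_sigma(self, profiles, body):
        kinect = self._clean_stream(profiles, body)
        err = SensorErrorModel(jitter_sd_mm=2.0, spike_prob=0.0,
                               channel_gain={c: 0.0 for c in CHANNELS})
        diffs = []
        for seed in range(40):
            out = corrupt(kinect, err, seed=seed)
            diffs.append(out.positions["ER"] - kinect.positions["ER"])
        sd = np.concatenate(diffs).std()
        assert sd == pytest.approx(2.0, rel=0.05)

    def test_systematic_part_is_seed_independent(self, profiles, body):
        kinect = self._clean_stream(profiles, body)
        err = SensorErrorModel(jitter_sd_mm=0.0, spike_prob=0.0)
        a = corrupt(kinect, err, seed=1)
        b = corrupt(kinect, err, seed=999)
        for n in kinect.positions:
            np.testing.assert_array_equal(a.positions[n], b.positions[n])

    def test_systematic_angle_error_is_smooth_function_of_truth(
            self, profiles, body):
        kinect = self._clean_stream(profiles, body)
        err = SensorErrorModel(jitter_sd_mm=0.0, spike_prob=0.0)
        out = corrupt(kinect, err, seed=0)
        delta = (kinematics_kinect(out).values
                 - kinematics_kinect(kinect).values)
        # deterministic and bounded: no wrap-around or fold-through jumps
        assert np.all(np.isfinite(delta))
        assert np.abs(delta).max() < 180.0
        assert np.abs(np.diff(delta, axis=0)).max() < 90.0


class TestGenerateCorpus:
    def test_counting_and_unique_keys(self):
        corpus = generate_corpus(n_subjects=3, trials_per_task=2,
                                 master_seed=5)
        assert len(corpus) == 3 * 4 * 2
        keys = {(t.subject_id, t.task, t.trial_id) for t in corpus}
        assert len(keys) == len(corpus)

    def test_master_seed_determinism(self):
        a = generate_corpus(n_subjects=3, tasks=("t4_back_pocket",),
                            trials_per_task=1, master_seed=8)
        b = generate_corpus(n_subjects=3, tasks=("t4_back_pocket",),
                            trials_per_task=1, master_seed=8)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.kinect_stream.positions["WR"],
                                          tb.kinect_stream.positions["WR"])
            np.testing.assert_array_equal(ta.truth_angles.values,
                                          tb.truth_angles.values)

    def test_plane_dependence_ie_error_exceeds_aa(self, default_corpus_small):
        from uplimb.synthetic import uncorrected_rmse

        r = uncorrected_rmse(default_corpus_small, "t3_comb_hair")
        assert r[CHANNELS.index("IE")] > r[CHANNELS.index("AA")]

    def test_truth_angles_attached_with_ids(self):
        corpus = generate_corpus(n_subjects=3, tasks=("t1_contralateral_shoulder",),
                                 trials_per_task=1, master_seed=2)
        for t in corpus:
            assert t.truth_angles.subject_id == t.subject_id
            assert t.truth_angles.task == t.task


class TestCalibration:
    def test_bisection_reaches_target(self):
        from uplimb.synthetic import calibrate_error_gain, uncorrected_rmse

        target = 20.0
        err = calibrate_error_gain({"FE": target}, n_subjects=4,
                                   trials_per_task=2, master_seed=6,
                                   tolerance=2.0, n_rounds=1)
        corpus = generate_corpus(n_subjects=4, tasks=("t3_comb_hair",),
                                 trials_per_task=2, err=err, master_seed=6)
        achieved = uncorrected_rmse(corpus, "t3_comb_hair")[0]
        assert achieved == pytest.approx(target, abs=2.0)

    def test_unreachable_target_raises_with_achieved_value(self):
        from uplimb.synthetic import calibrate_error_gain

        with pytest.raises(ValidationError, match="unreachable"):
            calibrate_error_gain({"FE": 0.01}, n_subjects=3,
                                 trials_per_task=1, master_seed=6,
                                 tolerance=0.005, n_rounds=1)
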