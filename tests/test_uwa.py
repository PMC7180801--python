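import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from uplimb.datamodel import LandmarkSeries, SingularGeometryError, ValidationError
from uplimb.kinect import compose_zxy
from uplimb.uwa import (
    cast_calibrate,
    cast_reconstruct,
    forearm_frame_uwa,
    joint_centers_uwa,
    kinematics_uwa,
    thorax_frame_uwa,
    upper_arm_frame_uwa,
)


class TestThoraxFrame:
    def test_hand_evaluated_example(self):
        f = thorax_frame_uwa(C7=(0, 500, -50), T10=(0, 0, -50),
                             CLAV=(0, 500, 50), STRN=(0, 0, 50))
        np.testing.assert_allclose(f.y, [0, 1, 0], atol=1e-12)
        # (C7-T10) x (CLAV-T10) = (0,500,0) x (0,500,100) -> +x; hint keeps it
        np.testing.assert_allclose(f.z, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.x, [0, 0, -1], atol=1e-12)
        np.testing.assert_allclose(f.origin, [0, 500, 0])

    def test_lateral_sign_follows_hint(self):
        f = thorax_frame_uwa(C7=(0, 500, -50), T10=(0, 0, -50),
                             CLAV=(0, 500, 50), STRN=(0, 0, 50),
                             right_hint=(-1, 0, 0))
        np.testing.assert_allclose(f.z, [-1, 0, 0], atol=1e-12)

    def test_coincident_markers_rejected(self):
        with pytest.raises(SingularGeometryError):
            thorax_frame_uwa(C7=(0, 500, 0), T10=(0, 0, 0),
                             CLAV=(0, 500, 0), STRN=(0, 0, 0))


class TestJointCenters:
    def test_shoulder_midpoint_without_acromion(self):
        S, E, W = joint_centers_uwa(PSH=(0, 0, -40), ASH=(0, 0, 40),
                                    EL=(30, 0, 0), EM=(-30, 0, 0),
                                    RS=(10, 0, 0), US=(-10, 0, 0))
        np.testing.assert_allclose(S, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(E, [0, 0, 0], atol=1e-12)

    def test_shoulder_centroid_with_acromion(self):
        pts = np.array([[1.0, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                        [-0.5, -np.sqrt(3) / 2, 0]]) * 40
        S, _, _ = joint_centers_uwa(PSH=pts[0], ASH=pts[1], ACR=pts[2],
                                    EL=(30, 0, 0), EM=(-30, 0, 0),
                                    RS=(10, 0, 0), US=(-10, 0, 0))
        np.testing.assert_allclose(S, pts.mean(axis=0), atol=1e-12)

    def test_single_shoulder_marker_rejected(self):
        with pytest.raises(ValidationError):
            joint_centers_uwa(PSH=(0, 0, 0), ASH=None, EL=(30, 0, 0),
                              EM=(-30, 0, 0), RS=(1, 0, 0), US=(-1, 0, 0))


class TestForearmFrame:
    def test_hand_evaluated_example(self):
        f = forearm_frame_uwa(E=(0, 260, 0), W=(0, 0, 0),
                              RS=(30, 0, 0), US=(-30, 0, 0))
        np.testing.assert_allclose(f.y, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.x, [0, 0, -1], atol=1e-12)
        np.testing.assert_allclose(f.z, [1, 0, 0], atol=1e-12)

    def test_coincident_styloids_rejected(self):
        with pytest.raises(SingularGeometryError):
            forearm_frame_uwa(E=(0, 260, 0), W=(0, 0, 0),
                              RS=(0, 0, 0), US=(0, 0, 0))

    def test_orthonormal_on_random_inputs(self, rng):
        kept = 0
        for _ in range(300):
            E, W, RS, US = rng.normal(0, 150, (4, 3))
            try:
                f = forearm_frame_uwa(E, W, RS, US)
            except SingularGeometryError:
                continue
            kept += 1
            np.testing.assert_allclose(f.axes.T @ f.axes, np.eye(3), atol=1e-9)
            assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-9)
        assert kept > 250

    def test_upper_arm_matches_kinect_construction(self):
        from uplimb.kinect import upper_arm_frame_kinect

        S, E, W = (0, 0, 0), (0, -300, 0), (250, -300, 0)
        np.testing.assert_allclose(upper_arm_frame_uwa(S, E, W).axes,
                                   upper_arm_frame_kinect(S, E, W).axes,
                                   atol=1e-12)


def _static_cluster_series(rng=None, T=20, noise=0.0, motion=None):
    """Cluster + landmark series; optional per-frame rigid motion."""
    rng = rng or np.random.default_rng(5)
    base = {
        "PUA1": np.array([0.0, 0.0, 0.0]),
        "PUA2": np.array([80.0, 10.0, 0.0]),
        "PUA3": np.array([20.0, 70.0, 30.0]),
        "DUA1": np.array([0.0, -300.0, 0.0]),
        "DUA2": np.array([70.0, -310.0, 10.0]),
        "DUA3": np.array([10.0, -250.0, 60.0]),
        "EM": np.array([-30.0, -150.0, 10.0]),
        "EL": np.array([40.0, -150.0, -10.0]),
        "RS": np.array([25.0, -420.0, 5.0]),
        "US": np.array([-25.0, -420.0, -5.0]),
    }
    positions = {}
    for name, p in base.items():
        traj = np.tile(p, (T, 1))
        if motion is not None:
            traj = np.array([R @ p + t for R, t in motion])
        if noise:
            traj = traj + rng.normal(0, noise, traj.shape)
        positions[name] = traj
    return LandmarkSeries(source="mocap", rate_hz=100.0, positions=positions,
                          times=np.arange(T) / 100.0)


class TestCast:
    def test_identity_frame_recovers_global_offsets(self):
        static = _static_cluster_series()
        cal = cast_calibrate(static)
        # PUA1 is the cluster origin with x toward PUA2
        np.testing.assert_allclose(
            np.linalg.norm(cal.local["EM"]),
            np.linalg.norm(static.positions["EM"][0] - static.positions["PUA1"][0]),
            atol=1e-9)

    def test_local_coordinates_rigid_invariant(self, rng):
        static = _static_cluster_series()
        cal0 = cast_calibrate(static)
        T = static.n_frames
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(0, 300, 3)
        moved = _static_cluster_series(motion=[(R, t)] * T)
        cal1 = cast_calibrate(moved)
        for name in cal0.local:
            np.testing.assert_allclose(cal1.local[name], cal0.local[name],
                                       atol=1e-9)

    def test_reconstruction_exact_under_rigid_motion(self, rng):
        static = _static_cluster_series()
        cal = cast_calibrate(static)
        T = 15
        motion = [(Rotation.random(random_state=i).as_matrix(),
                   rng.normal(0, 200, 3)) for i in range(T)]
        moved = _static_cluster_series(T=T, motion=motion)
        truth = {n: moved.positions[n] for n in ("EM", "EL", "RS", "US")}
        dynamic = LandmarkSeries(
            source="mocap", rate_hz=100.0,
            positions={n: v for n, v in moved.positions.items()
                       if n not in ("EM", "EL", "RS", "US")},
            times=moved.times)
        rec = cast_reconstruct(dynamic, cal)
        for n, v in truth.items():
            np.testing.assert_allclose(rec.positions[n], v, atol=1e-9)

    def test_noisy_static_averages_down(self, rng):
        sigma, T = 0.5, 200
        noisy = _static_cluster_series(rng=rng, T=T, noise=sigma)
        clean_cal = cast_calibrate(_static_cluster_series(T=4))
        noisy_cal = cast_calibrate(noisy)
        for name in clean_cal.local:
            err = np.linalg.norm(noisy_cal.local[name] - clean_cal.local[name])
            assert err < 6 * sigma / np.sqrt(T)  # ~3 sigma per axis, summed


class TestKinematicsUwa:
    def test_noise_free_trial_recovers_truth(self, clean_trial):
        from scipy.interpolate import CubicSpline

        wf = kinematics_uwa(clean_trial)
        truth = clean_trial.truth_angles
        spline = CubicSpline(truth.meta["times"], truth.values, axis=0)
        expected = spline(clean_trial.mocap_stream.times)
        np.testing.assert_allclose(wf.values, expected, atol=1e-6)

    def test_pure_elbow_rotation_decomposes_on_z_only(self):
        from uplimb.kinect import decompose_zxy

        R = compose_zxy(45.0, 0.0, 0.0)
        fe, aa, ie, _ = decompose_zxy(R)
        assert fe == pytest.approx(45.0, abs=1e-12)
        assert aa == pytest.approx(0.0, abs=1e-12)
        assert ie == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, clean_trial, rng):
        base = kinematics_uwa(clean_trial)
        R = Rotation.random(random_state=11).as_matrix()
        t = rng.normal(0, 400, 3)

        def move(series):
            return LandmarkSeries(
                source=series.source, rate_hz=series.rate_hz,
                positions={k: v @ R.T + t for k, v in series.positions.items()},
                times=series.times)

        wf = kinematics_uwa(move(clean_trial.mocap_stream),
                            static=move(clean_trial.static_trial))
        np.testing.assert_allclose(wf.values, base.values, atol=1e-6)
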