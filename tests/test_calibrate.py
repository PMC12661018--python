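import numpy as np
import pytest

from thighacc import (
    TriaxialRecording,
    apply_calibration,
    autocalibrate_device,
    individual_calibration,
    simulate_recording,
)
from thighacc.calibrate import CalibrationParams
from thighacc.preprocess import extract_features
from thighacc.simulator import BehaviourScript


def rotation_about_v(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])


def rotation_angle_deg(R):
    return float(np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0))))


@pytest.fixture(scope="module")
def walking_dominant():
    """Free-living-like session: walking dominates locomotion time, as it
    does in real wear, so the gait-attitude reference is identifiable."""
    segs = []
    for _ in range(6):
        segs += [("sedentary", 120.0), ("walk", 90.0), ("stand", 60.0), ("move", 30.0)]
    segs += [("stairs", 40.0), ("cycle", 60.0)]
    rec, truth = simulate_recording(BehaviourScript(segs), fs_hz=25.0, seed=5)
    return rec, truth


class TestAutocalibration:
    def test_already_calibrated_recovers_identity(self, still_pose_recording):
        cal = autocalibrate_device(still_pose_recording)
        np.testing.assert_allclose(cal.gain, 1.0, atol=1e-4)
        np.testing.assert_allclose(cal.offset, 0.0, atol=1e-4)

    def test_known_distortion_recovered(self, still_pose_recording):
        gain = np.array([1.05, 0.97, 1.02])
        offset = np.array([0.02, -0.03, 0.01])
        distorted = still_pose_recording.with_samples(
            still_pose_recording.samples * gain + offset
        )
        cal = autocalibrate_device(distorted)
        np.testing.assert_allclose(cal.gain, gain, atol=1e-3)
        np.testing.assert_allclose(cal.offset, offset, atol=1e-3)
        assert not cal.flags

    def test_single_orientation_flagged_identity(self, device25):
        rec = TriaxialRecording(device25, 0.0, 25.0, np.tile([1.0, 0.0, 0.0], (2000, 1)))
        cal = autocalibrate_device(rec)
        assert "sphere fit underdetermined" in cal.flags
        np.testing.assert_array_equal(cal.gain, 1.0)

    def test_self_consistency_on_own_stills(self, still_pose_recording):
        distorted = still_pose_recording.with_samples(
            still_pose_recording.samples * [1.04, 0.95, 1.01] + [0.01, -0.02, 0.03]
        )
        cal = autocalibrate_device(distorted)
        fixed = apply_calibration(distorted, cal)
        mags = np.linalg.norm(fixed.samples, axis=1)
        np.testing.assert_allclose(mags, 1.0, atol=1e-3)


class TestIndividualCalibration:
    def test_mounting_rotation_recovered(self, walking_dominant):
        rec, _ = walking_dominant
        Rv = rotation_about_v(15.0)
        rotated = rec.with_samples(rec.samples @ Rv.T)
        cal_rot = individual_calibration(extract_features(rotated))
        cal_plain = individual_calibration(extract_features(rec))
        # mounting-only component: R(rotated) composed with the known
        # rotation should reproduce the plain-recording calibration
        residual = cal_rot.rotation @ Rv @ cal_plain.rotation.T
        assert rotation_angle_deg(residual) < 1.0

    def test_perfect_mounting_near_identity(self, walking_dominant):
        rec, _ = walking_dominant
        cal = individual_calibration(extract_features(rec))
        # residual is the gap between this subject's gait lean and the canonical 20 deg
        assert rotation_angle_deg(cal.rotation) < 2.0

    def test_upside_down_detected_and_fixed(self, walking_dominant):
        rec, truth = walking_dominant
        flipped = rec.with_samples(rec.samples @ np.diag([-1.0, -1.0, 1.0]))
        cal = individual_calibration(extract_features(flipped))
        assert "upside-down mounting detected" in cal.flags
        fixed = apply_calibration(flipped, cal)
        feats = extract_features(fixed)
        stand_incl = np.median(
            [
                f.inclination_deg
                for f in feats
                if truth.labels[min(f.epoch_index, len(truth) - 1)] == "stand"
            ]
        )
        assert stand_incl < 15.0

    def test_too_few_reference_epochs_flagged(self):
        rec, _ = simulate_recording(BehaviourScript([("sedentary", 120.0)]), seed=1)
        cal = individual_calibration(extract_features(rec))
        assert "too few reference epochs" in cal.flags
        np.testing.assert_array_equal(cal.rotation, np.eye(3))


class TestApplyCalibration:
    def test_identity_is_noop(self, walking_dominant):
        rec, _ = walking_dominant
        out = apply_calibration(rec, CalibrationParams.identity())
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_rotation_composition(self, walking_dominant):
        rec, _ = walking_dominant
        r1 = CalibrationParams(rotation=rotation_about_v(10.0))
        r2 = CalibrationParams(rotation=rotation_about_v(-25.0))
        seq = apply_calibration(apply_calibration(rec, r1), r2)
        combined = CalibrationParams(rotation=rotation_about_v(-25.0) @ rotation_about_v(10.0))
        out = apply_calibration(rec, combined)
        np.testing.assert_allclose(seq.samples, out.samples, atol=1e-9)

    def test_preserves_epoch_count(self, walking_dominant):
        rec, _ = walking_dominant
        cal = CalibrationParams(gain=[1.1, 0.9, 1.0], offset=[0.05, 0.0, -0.02])
        out = apply_calibration(rec, cal)
        assert out.n_samples == rec.n_samples
        assert out.fs_hz == rec.fs_hz
        assert out.start_time == rec.start_time

    def test_full_chain_static_inclination_error_small(self, walking_dominant, still_pose_recording):
        """Known gain/offset/rotation distortions: after autocalibration
        (from diverse stills) plus individual calibration, static-posture
        inclination is recovered to within 2 degrees."""
        rec, truth = walking_dominant
        gain = np.array([1.05, 0.97, 1.02])
        offset = np.array([0.02, -0.03, 0.01])
        Rv = rotation_about_v(12.0)
        distorted_motion = rec.with_samples((rec.samples @ Rv.T) * gain + offset)
        distorted_stills = still_pose_recording.with_samples(
            still_pose_recording.samples * gain + offset
        )
        auto = autocalibrate_device(distorted_stills)
        step1 = apply_calibration(distorted_motion, auto)
        ind = individual_calibration(extract_features(step1))
        full = apply_calibration(step1, ind)
        feats = extract_features(full)
        for beh, true_incl in (("sedentary", 75.0), ("stand", 10.0)):
            med = np.median(
                [
                    f.inclination_deg
                    for f in feats
                    if truth.labels[min(f.epoch_index, len(truth) - 1)] == beh
                ]
            )
            assert med == pytest.approx(true_incl, abs=2.0)

    def test_params_json_round_trip(self, tmp_path):
        cal = CalibrationParams(
            gain=[1.02, 0.98, 1.0], offset=[0.01, -0.01, 0.0],
            rotation=rotation_about_v(7.0), residual=0.003, flags=["x"],
        )
        p = tmp_path / "cal.json"
        cal.to_json(p)
        back = CalibrationParams.from_json(p)
        np.testing.assert_allclose(back.rotation, cal.rotation, atol=1e-12)
        np.testing.assert_allclose(back.gain, cal.gain)
        assert back.flags == ["x"]

    def test_sanity_bounds_enforced(self):
        with pytest.raises(ValueError, match="gains"):
            CalibrationParams(gain=[3.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="offsets"):
            CalibrationParams(offset=[0.0, 0.9, 0.0])
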