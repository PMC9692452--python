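"""Wrist kinematics: calibration, the three angle measures, and scores."""

import numpy as np
import pytest

from ergorula.geometry import rotation_matrix
from ergorula.skeleton import DEFAULT_HAND_REGISTRY, HandFrame, Stream
from ergorula.synth import HAND_TEMPLATE, WristTargets, solve_hand_pose
from ergorula.wrist import (
    CalibrationError,
    calibrate,
    flexion_extension,
    pronation_supination,
    radial_ulnar,
    wrist_angles,
    wrist_position_score,
    wrist_twist_score,
)


def hand_stream(*poses):
    """Stream whose frames place the same (25,3) pose on both hands."""
    coords = np.stack([np.vstack([p, p]) for p in poses])
    ts = np.arange(len(poses)) / 64.0
    return Stream(ts, coords, "hand", DEFAULT_HAND_REGISTRY, 64.0)


def hand_frame(pose):
    return HandFrame(0.0, np.vstack([pose, pose]), DEFAULT_HAND_REGISTRY)


@pytest.fixture(scope="module")
def neutral_cal():
    return calibrate(hand_stream(HAND_TEMPLATE))


class TestCalibrate:
    def test_first_valid_frame_is_frame_zero(self, neutral_cal):
        for side in ("left", "right"):
            assert neutral_cal[side].frame_index == 0

    def test_dropout_in_first_frame_moves_to_next(self):
        broken = HAND_TEMPLATE.copy()
        broken[24] = np.nan  # pinky metacarpal endpoint missing
        cal = calibrate(hand_stream(broken, HAND_TEMPLATE))
        assert cal["right"].frame_index == 1

    def test_missing_side_raises_naming_it(self):
        coords = np.stack([np.vstack([np.full((25, 3), np.nan),
                                      HAND_TEMPLATE])] * 3)
        stream = Stream(np.arange(3) / 64.0, coords, "hand",
                        DEFAULT_HAND_REGISTRY, 64.0)
        with pytest.raises(CalibrationError, match="left"):
            calibrate(stream)


class TestFlexionExtension:
    def test_literal_45_degrees(self, neutral_cal):
        pose = HAND_TEMPLATE.copy()
        pose[13] = (0.0, 1.0, 1.0)   # x13
        pose[14] = (0.0, 1.0, 0.0)   # x14
        fe = flexion_extension(hand_frame(pose), "right", neutral_cal)
        assert fe == pytest.approx(45.0, abs=1e-9)  # up => positive

    def test_collinear_from_origin_is_zero(self, neutral_cal):
        fe = flexion_extension(hand_frame(HAND_TEMPLATE), "right",
                               neutral_cal)
        assert fe == pytest.approx(0.0, abs=1e-9)

    def test_recentered_straight_chain_is_zero(self, neutral_cal):
        pose = HAND_TEMPLATE.copy()
        pose[0] = (5.0, 10.0, 0.0)             # wrist-reference joint
        pose[13] = pose[0] + (0.0, 120.0, 0.0)
        pose[14] = pose[0] + (0.0, 60.0, 0.0)
        frame = hand_frame(pose)
        assert flexion_extension(frame, "right", neutral_cal,
                                 mode="recentered") == pytest.approx(0.0)
        # the literal reading of the same pose is origin-dependent
        assert flexion_extension(frame, "right", neutral_cal) > 0.5

    def test_flexion_is_negative(self, neutral_cal):
        pose = solve_hand_pose(WristTargets(flexion_extension=-25.0))
        fe = flexion_extension(hand_frame(pose), "right", neutral_cal)
        assert fe == pytest.approx(-25.0, abs=1e-6)

    def test_missing_joint_unscorable(self, neutral_cal):
        pose = HAND_TEMPLATE.copy()
        pose[14] = np.nan
        assert flexion_extension(hand_frame(pose), "right",
                                 neutral_cal) is None


class TestRadialUlnar:
    def test_calibration_pose_reads_zero(self, neutral_cal):
        assert radial_ulnar(hand_frame(HAND_TEMPLATE), "right",
                            neutral_cal) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("dev", [5.0, 20.0, 40.0])
    def test_constructed_deviation_recovered(self, dev, neutral_cal):
        pose = solve_hand_pose(WristTargets(radial_ulnar=dev))
        assert radial_ulnar(hand_frame(pose), "right",
                            neutral_cal) == pytest.approx(dev, abs=1e-6)

    def test_coincident_joints_unscorable(self, neutral_cal):
        pose = HAND_TEMPLATE.copy()
        pose[5] = pose[4]  # degenerate chain: x05 coincides with x04
        assert radial_ulnar(hand_frame(pose), "right", neutral_cal) is None


class TestPronationSupination:
    def test_calibration_frame_reads_zero(self, neutral_cal):
        assert pronation_supination(hand_frame(HAND_TEMPLATE), "right",
                                    neutral_cal) == pytest.approx(0.0)

    @pytest.mark.parametrize("delta", [10.0, 90.0, 130.0, 175.0])
    def test_forearm_rotation_recovered(self, delta, neutral_cal):
        """Rotating the whole hand about the forearm axis by delta moves
        the palm normal by exactly delta."""
        R = rotation_matrix([0.0, 1.0, 0.0], delta)
        pose = HAND_TEMPLATE @ R.T
        assert pronation_supination(hand_frame(pose), "right",
                                    neutral_cal) == pytest.approx(delta,
                                                                  abs=1e-6)

    def test_rotation_beyond_180_folds(self, neutral_cal):
        R = rotation_matrix([0.0, 1.0, 0.0], 200.0)
        pose = HAND_TEMPLATE @ R.T
        assert pronation_supination(hand_frame(pose), "right",
                                    neutral_cal) == pytest.approx(160.0,
                                                                  abs=1e-6)


class TestInvariances:
    def test_translation_invariance(self, neutral_cal):
        pose = solve_hand_pose(
            WristTargets(flexion_extension=20.0, radial_ulnar=10.0)
        )
        shifted = pose + np.array([123.0, -45.0, 67.0])
        f0, f1 = hand_frame(pose), hand_frame(shifted)
        assert radial_ulnar(f1, "right", neutral_cal) == pytest.approx(
            radial_ulnar(f0, "right", neutral_cal), abs=1e-9
        )
        assert pronation_supination(f1, "right", neutral_cal) == pytest.approx(
            pronation_supination(f0, "right", neutral_cal), abs=1e-9
        )
        # recentered flexion-extension is translation-invariant by design
        assert flexion_extension(
            f1, "right", neutral_cal, mode="recentered"
        ) == pytest.approx(
            flexion_extension(f0, "right", neutral_cal, mode="recentered"),
            abs=1e-9,
        )

    def test_pronation_invariant_under_common_rotation(self):
        R = rotation_matrix([1.0, 2.0, 0.5], 33.0)
        pose = solve_hand_pose(WristTargets(pronation_supination=70.0))
        cal_rot = calibrate(hand_stream(HAND_TEMPLATE @ R.T))
        ps = pronation_supination(hand_frame(pose @ R.T), "right", cal_rot)
        assert ps == pytest.approx(70.0, abs=1e-6)


class TestScores:
    @pytest.mark.parametrize(
        "fe, ru, expected",
        [
            (0.0, 0.0, 1),     # neutral band
            (10.0, 0.0, 2),
            (15.0, 0.0, 2),    # band edge: 15 deg is still the +2 band
            (-10.0, 0.0, 2),
            (25.0, 0.0, 3),    # >15 deg up
            (-25.0, 0.0, 3),   # >15 deg down
            (25.0, 20.0, 4),   # +1 bent from midline, capped at 4
            (0.0, 20.0, 2),
            (0.0, 14.9, 1),    # below the 15 deg deviation threshold
        ],
    )
    def test_position_bands(self, fe, ru, expected):
        assert wrist_position_score(fe, ru) == expected

    def test_position_score_monotone(self):
        grid = np.linspace(0.0, 60.0, 25)
        for ru in (0.0, 20.0):
            scores = [wrist_position_score(fe, ru) for fe in grid]
            assert scores == sorted(scores)
        assert all(
            wrist_position_score(fe, 20.0) >= wrist_position_score(fe, 0.0)
            for fe in grid
        )

    @pytest.mark.parametrize(
        "ps, expected",
        [(90.0, 1), (130.0, 2), (0.0, 1), (105.0, 1), (110.0, 2),
         (170.0, 2)],
    )
    def test_twist_bands(self, ps, expected):
        assert wrist_twist_score(ps) == expected

    def test_twist_outside_range_rejected(self):
        with pytest.raises(ValueError):
            wrist_twist_score(200.0)

    def test_wrist_angles_bundles_all_three(self, neutral_cal):
        wa = wrist_angles(hand_frame(HAND_TEMPLATE), "left", neutral_cal)
        assert wa.side == "left"
        assert wa.flexion_extension == pytest.approx(0.0, abs=1e-9)
        assert wa.radial_ulnar == pytest.approx(0.0, abs=1e-9)
        assert wa.pronation_supination == pytest.approx(0.0, abs=1e-9)
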