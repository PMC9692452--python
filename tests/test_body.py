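"""Body-segment scoring: printed bands, adjustments and sign conventions."""

import numpy as np
import pytest
from dataclasses import replace

from ergorula.body import (
    legs_score,
    lower_arm_base,
    lower_arm_score,
    neck_base,
    neck_score,
    trunk_base,
    trunk_score,
    upper_arm_base,
    upper_arm_score,
)
from ergorula.skeleton import DEFAULT_BODY_REGISTRY, BodyFrame
from ergorula.synth import ArmTargets, PostureSpec, solve_body_pose

FREE_ARM = ArmTargets(position=10.0, shoulder_raise=None, abduction=None,
                      elbow=80.0, across_midline=None)


def body_frame(spec: PostureSpec) -> BodyFrame:
    return BodyFrame(0.0, solve_body_pose(spec), DEFAULT_BODY_REGISTRY)


class TestPrintedBands:
    """Direct band mappings against the worksheet values."""

    @pytest.mark.parametrize(
        "angle, expected",
        [(0, 1), (10, 1), (-10, 1), (-30, 2), (30, 2), (45, 3), (60, 3),
         (90, 4), (120, 4)],
    )
    def test_upper_arm(self, angle, expected):
        assert upper_arm_base(angle) == expected

    @pytest.mark.parametrize(
        "angle, expected", [(80, 1), (60, 1), (30, 2), (0, 2), (100, 2),
                            (150, 2)]
    )
    def test_lower_arm(self, angle, expected):
        assert lower_arm_base(angle) == expected

    @pytest.mark.parametrize(
        "angle, expected", [(5, 1), (0, 1), (15, 2), (30, 3), (20, 3),
                            (-5, 4)]
    )
    def test_neck(self, angle, expected):
        assert neck_base(angle) == expected

    @pytest.mark.parametrize(
        "angle, expected", [(0, 1), (0.5, 1), (10, 2), (40, 3), (20, 3),
                            (70, 4), (60, 4)]
    )
    def test_trunk(self, angle, expected):
        assert trunk_base(angle) == expected


class TestFixtureScoring:
    """Scores measured from constructed skeletons, not raw angles."""

    def test_upper_arm_120_scores_base_4(self):
        spec = replace(
            PostureSpec(),
            right_arm=ArmTargets(position=120.0, shoulder_raise=85.0,
                                 abduction=None, elbow=80.0,
                                 across_midline=None),
        )
        s = upper_arm_score(body_frame(spec), "right")
        assert s.base == 4
        assert s.components["shoulder_raised"] == 0  # 85 <= 90

    def test_both_arm_adjustments_add_and_cap(self):
        spec = replace(
            PostureSpec(),
            right_arm=ArmTargets(position=120.0, shoulder_raise=100.0,
                                 abduction=50.0, elbow=80.0,
                                 across_midline=None),
        )
        s = upper_arm_score(body_frame(spec), "right")
        assert s.base == 4
        assert s.components == {"shoulder_raised": 1, "abducted": 1}
        assert s.score == 6

    def test_lower_arm_80_with_inactive_adjustments_scores_1(self):
        spec = replace(
            PostureSpec(),
            right_arm=ArmTargets(position=10.0, shoulder_raise=None,
                                 abduction=None, elbow=80.0,
                                 across_midline=60.0),
        )
        s = lower_arm_score(body_frame(spec), "right")
        assert s.score == 1 and s.components == {"across_midline": 0,
                                                 "out_to_side": 0}

    def test_across_midline_adjustment_fires(self):
        spec = replace(
            PostureSpec(),
            right_arm=ArmTargets(position=10.0, shoulder_raise=None,
                                 abduction=None, elbow=80.0,
                                 across_midline=95.0),
        )
        s = lower_arm_score(body_frame(spec), "right")
        assert s.base == 1 and s.components["across_midline"] == 1
        assert s.score == 2

    def test_out_to_side_shares_upper_arm_formula(self):
        # the printed out-to-side joints coincide with the upper-arm
        # position joints, so a 60 deg position angle fires it
        spec = replace(
            PostureSpec(),
            right_arm=ArmTargets(position=60.0, shoulder_raise=None,
                                 abduction=None, elbow=80.0,
                                 across_midline=None),
        )
        s = lower_arm_score(body_frame(spec), "right")
        assert s.components["out_to_side"] == 1

    @pytest.mark.parametrize("nu, expected", [(5.0, 1), (30.0, 3), (-5.0, 4)])
    def test_neck_bands_from_fixtures(self, nu, expected):
        spec = replace(PostureSpec(), neck_position=nu, right_arm=FREE_ARM,
                       left_arm=FREE_ARM)
        assert neck_score(body_frame(spec)).score == expected

    def test_neck_side_bending_adds_one(self):
        spec = replace(PostureSpec(), neck_side_bend=25.0,
                       right_arm=FREE_ARM, left_arm=FREE_ARM)
        s = neck_score(body_frame(spec))
        assert s.components["side_bending"] == 1 and s.score == 2

    @pytest.mark.parametrize("tau, expected", [(0.0, 1), (40.0, 3)])
    def test_trunk_bands_from_fixtures(self, tau, expected):
        spec = replace(PostureSpec(), trunk_position=tau)
        assert trunk_score(body_frame(spec)).score == expected

    def test_trunk_flexed_plus_side_bend(self):
        spec = replace(PostureSpec(), trunk_position=40.0,
                       trunk_side_bend_right=25.0)
        s = trunk_score(body_frame(spec))
        assert s.base == 3 and s.components["side_bending"] == 1
        assert s.score == 4

    def test_trunk_twist_requires_bent_hips_and_adds_one(self):
        spec = replace(
            PostureSpec(), trunk_twist=22.0, trunk_side_bend_right=30.0,
            trunk_side_bend_left=30.0, neck_position=None,
            right_arm=FREE_ARM, left_arm=FREE_ARM,
        )
        s = trunk_score(body_frame(spec))
        assert s.components == {"twisted": 1, "side_bending": 1}
        assert s.score == 3

    def test_missing_joint_makes_segment_unscorable(self):
        frame = body_frame(PostureSpec())
        coords = frame.coords.copy()
        coords[6] = np.nan  # right shoulder
        broken = BodyFrame(0.0, coords, DEFAULT_BODY_REGISTRY)
        assert upper_arm_score(broken, "right") is None
        assert neck_score(broken) is not None  # neck chain intact


class TestLegs:
    def test_standing_unsupported_scores_2(self):
        assert legs_score().score == 2

    def test_supported_and_balanced_scores_1(self):
        assert legs_score(standing_unsupported=False).score == 1

    def test_constant_across_frames(self, scored_session):
        _, results, *_ = scored_session
        assert {r.segments["legs"] for r in results} == {2}


class TestCodomains:
    def test_scores_respect_rula_ranges_on_jittered_skeletons(self):
        spec = replace(PostureSpec(), jitter_sd=3.0)
        rng = np.random.default_rng(11)
        from ergorula.synth import make_posture_frames

        body, _ = make_posture_frames(spec, rng=rng)
        for frame in body.frames():
            for side in ("left", "right"):
                ua = upper_arm_score(frame, side)
                la = lower_arm_score(frame, side)
                assert ua is None or 1 <= ua.score <= 6
                assert la is None or 1 <= la.score <= 3
            nk, tr = neck_score(frame), trunk_score(frame)
            assert nk is None or 1 <= nk.score <= 6
            assert tr is None or 1 <= tr.score <= 6
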