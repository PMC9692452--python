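"""Fixture generator: exact angle realisation, determinism, noise models."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from ergorula.skeleton import ActivityLabel
from ergorula.synth import (
    ArmTargets,
    FeasibilityError,
    PostureSpec,
    SessionSpec,
    WristTargets,
    achieved_angles,
    demo_session,
    make_posture_frames,
    make_session,
    solve_hand_pose,
    true_scores,
)

FREE_ARM = ArmTargets(position=10.0, shoulder_raise=None, abduction=None,
                      elbow=80.0, across_midline=None)


def spec_with(**kw) -> PostureSpec:
    base = PostureSpec(right_arm=FREE_ARM, left_arm=FREE_ARM)
    return replace(base, **kw)


class TestExactRealisation:
    """Every targeted formula evaluates to its target within 1e-6 deg."""

    @pytest.mark.parametrize(
        "field, target",
        [
            ("trunk_position", 0.0), ("trunk_position", 10.0),
            ("trunk_position", 40.0), ("trunk_position", 70.0),
            ("neck_position", 5.0), ("neck_position", 15.0),
            ("neck_position", 30.0), ("neck_position", -5.0),
            ("neck_side_bend", 25.0),
        ],
    )
    def test_torso_targets(self, field, target):
        spec = spec_with(**{field: target})
        assert achieved_angles(spec)[field] == pytest.approx(target,
                                                             abs=1e-6)

    @pytest.mark.parametrize(
        "arm, keys",
        [
            (ArmTargets(10.0, 20.0, 15.0, 80.0, None),
             {"upper_arm": 10.0, "shoulder_raise": 20.0, "abduction": 15.0,
              "lower_arm": 80.0}),
            (ArmTargets(-30.0, None, None, 80.0, None),
             {"upper_arm": -30.0}),
            (ArmTargets(60.0, None, None, 40.0, None),
             {"upper_arm": 60.0, "lower_arm": 40.0}),
            (ArmTargets(120.0, 100.0, 50.0, 80.0, None),
             {"upper_arm": 120.0, "shoulder_raise": 100.0,
              "abduction": 50.0}),
            (ArmTargets(10.0, None, None, 30.0, None), {"lower_arm": 30.0}),
            (ArmTargets(10.0, None, None, 120.0, None),
             {"lower_arm": 120.0}),
            (ArmTargets(10.0, None, None, 80.0, 60.0),
             {"across_midline": 60.0}),
            (ArmTargets(10.0, None, None, 80.0, 95.0),
             {"across_midline": 95.0}),
        ],
    )
    def test_right_arm_targets(self, arm, keys):
        spec = spec_with(right_arm=arm)
        ang = achieved_angles(spec)
        for key, want in keys.items():
            assert ang[f"{key}_right"] == pytest.approx(want, abs=1e-6), key

    @pytest.mark.parametrize(
        "arm, keys",
        [
            (ArmTargets(10.0, None, None, 80.0, None),
             {"upper_arm": 10.0, "lower_arm": 80.0}),
            (ArmTargets(60.0, None, None, 40.0, None),
             {"upper_arm": 60.0, "lower_arm": 40.0}),
            (ArmTargets(10.0, 95.0, None, 80.0, None),
             {"shoulder_raise": 95.0}),
        ],
    )
    def test_left_arm_targets(self, arm, keys):
        spec = spec_with(left_arm=arm)
        ang = achieved_angles(spec)
        for key, want in keys.items():
            assert ang[f"{key}_left"] == pytest.approx(want, abs=1e-6), key

    @pytest.mark.parametrize(
        "wt",
        [
            WristTargets(0.0, 0.0, 0.0),
            WristTargets(25.0, 0.0),
            WristTargets(-25.0, 20.0),
            WristTargets(0.0, 0.0, 90.0),
            WristTargets(0.0, 20.0, 130.0),
            WristTargets(0.0, 0.0, 175.0),
        ],
    )
    def test_wrist_targets(self, wt):
        spec = spec_with(right_wrist=wt)
        ang = achieved_angles(spec)
        assert ang["flexion_extension_right"] == pytest.approx(
            wt.flexion_extension, abs=1e-6)
        assert ang["radial_ulnar_right"] == pytest.approx(
            wt.radial_ulnar, abs=1e-6)
        if wt.pronation_supination is not None:
            assert ang["pronation_supination_right"] == pytest.approx(
                wt.pronation_supination, abs=1e-6)

    def test_flexion_tilts_the_palm_normal(self):
        # the lifted joint is part of the palm plane, so flexion alone
        # moves the pronation-supination reading off zero
        ang = achieved_angles(spec_with(right_wrist=WristTargets(25.0)))
        assert ang["pronation_supination_right"] > 10.0

    def test_inconsistent_flexion_and_pronation_rejected(self):
        with pytest.raises(FeasibilityError):
            solve_hand_pose(WristTargets(25.0, 0.0, 0.0))

    def test_infeasible_combination_raises(self):
        # the trunk-twist metric is bounded by the hip chain angles; a
        # 25 deg twist with near-straight hips cannot exist
        with pytest.raises(FeasibilityError):
            achieved_angles(spec_with(trunk_twist=25.0))


class TestBandRecovery:
    """Generate -> score recovers the intended band for every printed
    band of the posture and wrist tables (noise-free round trip)."""

    UPPER = [(10.0, 1), (-30.0, 2), (30.0, 2), (60.0, 3), (120.0, 4)]
    LOWER = [(80.0, 1), (30.0, 2), (120.0, 2)]
    NECK = [(5.0, 1), (15.0, 2), (30.0, 3), (-5.0, 4)]
    TRUNK = [(0.0, 1), (10.0, 2), (40.0, 3), (70.0, 4)]
    FE = [(0.0, 1), (10.0, 2), (25.0, 3)]
    PS = [(90.0, 1), (130.0, 2)]

    @pytest.mark.parametrize("target, band", UPPER)
    def test_upper_arm_bands(self, target, band):
        spec = spec_with(right_arm=replace(FREE_ARM, position=target))
        assert true_scores(spec)["upper_arm_right"] >= band  # adjustments add
        from ergorula.body import upper_arm_base

        assert upper_arm_base(
            achieved_angles(spec)["upper_arm_right"]) == band

    @pytest.mark.parametrize("target, band", LOWER)
    def test_lower_arm_bands(self, target, band):
        from ergorula.body import lower_arm_base

        spec = spec_with(right_arm=replace(FREE_ARM, elbow=target))
        assert lower_arm_base(achieved_angles(spec)["lower_arm_right"]) == band

    @pytest.mark.parametrize("target, band", NECK)
    def test_neck_bands(self, target, band):
        spec = spec_with(neck_position=target)
        assert true_scores(spec)["neck"] == band

    @pytest.mark.parametrize("target, band", TRUNK)
    def test_trunk_bands(self, target, band):
        spec = spec_with(trunk_position=target)
        assert true_scores(spec)["trunk"] == band

    @pytest.mark.parametrize("target, band", FE)
    def test_wrist_position_bands(self, target, band):
        spec = spec_with(right_wrist=WristTargets(flexion_extension=target))
        assert true_scores(spec)["wrist_position_right"] == band

    def test_deviation_adjustment(self):
        spec = spec_with(right_wrist=WristTargets(10.0, 20.0))
        assert true_scores(spec)["wrist_position_right"] == 3  # 2 + 1

    @pytest.mark.parametrize("target, band", PS)
    def test_wrist_twist_bands(self, target, band):
        spec = spec_with(
            right_wrist=WristTargets(pronation_supination=target))
        assert true_scores(spec)["wrist_twist_right"] == band


class TestStreams:
    def test_rates_and_frame_counts(self):
        spec = spec_with(duration=10.0)
        body, hand = make_posture_frames(spec)
        assert len(body) == 300 and body.nominal_rate == 30.0
        assert len(hand) == 640 and hand.nominal_rate == 64.0

    def test_same_seed_bit_identical(self, tmp_path):
        session = demo_session(segment_duration=0.5, jitter_sd=1.0,
                               null_rate=0.02)
        p1 = make_session(session, tmp_path / "a", seed=9)
        p2 = make_session(session, tmp_path / "b", seed=9)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_null_rate_within_binomial_bounds(self):
        rate = 0.05
        spec = spec_with(duration=4.0, null_rate=rate)
        body, hand = make_posture_frames(
            spec, rng=np.random.default_rng(21))
        dropped = np.isnan(body.coords[..., 0]).mean()
        n = body.coords[..., 0].size
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(dropped - rate) < 3 * se

    def test_jitter_perturbs_angles_but_preserves_lengths(self):
        spec = spec_with(jitter_sd=2.0)
        body, _ = make_posture_frames(spec, rng=np.random.default_rng(3))
        clean, _ = make_posture_frames(spec_with(),
                                       rng=np.random.default_rng(3))
        # distances from the waist are preserved by rotational jitter
        for i in (0, 6, 8):
            d_noisy = np.linalg.norm(body.coords[0, i] - body.coords[0, 3])
            d_clean = np.linalg.norm(clean.coords[0, i] - clean.coords[0, 3])
            assert d_noisy == pytest.approx(d_clean, rel=1e-9)
        assert not np.allclose(body.coords[0], clean.coords[0])

    def test_session_has_five_label_strata(self, session_paths):
        labels = pd.read_csv(session_paths["labels"])
        assert len(labels) == 5
        assert labels["low"].isin(
            {"grasp", "transport loaded", "assemble", "inspect", "position",
             "release load"}
        ).all()

    def test_expert_stride(self, scored_session, tmp_path):
        from ergorula.evaluation import REPORT_COLUMNS
        from ergorula.synth import make_expert_file

        _, _, scores_df, _, _ = scored_session
        expert = make_expert_file(scores_df, tmp_path / "e.csv", stride=10,
                                  disagreement_rate=0.0, seed=0)
        n_frames = int(np.ceil(len(scores_df) / 10))
        assert len(expert) == n_frames * len(REPORT_COLUMNS)

    def test_invalid_session_rejected(self):
        with pytest.raises(ValueError):
            SessionSpec(segments=())
        with pytest.raises(ValueError):
            PostureSpec(null_rate=1.5)
        with pytest.raises(FeasibilityError):
            PostureSpec(right_wrist=WristTargets(pronation_supination=200.0))
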