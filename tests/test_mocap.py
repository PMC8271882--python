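import numpy as np
import pytest

from ehecco import (
    GeneratorConfig,
    flatten_poses,
    forward_kinematics,
    generate_record,
    hip_normalize,
    unflatten_poses,
    write_bvh,
)
from ehecco.errors import BVHParseError, DimensionMismatchError
from ehecco.mocap import (
    Joint,
    MotionSequence,
    PoseSequence,
    SkeletonHierarchy,
    format_bvh,
    parse_bvh,
    poses_to_csv,
    read_bvh,
)

MINIMAL_BVH = """\
HIERARCHY
ROOT Hips
{
\tOFFSET 0.0 0.0 0.0
\tCHANNELS 6 Xposition Yposition Zposition Zrotation Xrotation Yrotation
\tJOINT Chest
\t{
\t\tOFFSET 0.0 10.0 0.0
\t\tCHANNELS 3 Zrotation Xrotation Yrotation
\t\tEnd Site
\t\t{
\t\t\tOFFSET 0.0 5.0 0.0
\t\t}
\t}
}
MOTION
Frames: 2
Frame Time: 0.033333
1 2 3 0 0 0 0 0 0
4 5 6 10 20 30 5 5 5
"""


def two_joint_hierarchy(offset=(1.0, 0.0, 0.0), root_channels=None, child_channels=None):
    root_channels = root_channels or (
        "Xposition", "Yposition", "Zposition", "Zrotation", "Xrotation", "Yrotation",
    )
    child_channels = child_channels or ("Zrotation", "Xrotation", "Yrotation")
    child = Joint(name="Child", offset=offset, channels=child_channels)
    root = Joint(name="Root", offset=(0, 0, 0), channels=root_channels, children=[child])
    return SkeletonHierarchy(root=root)


class TestParsing:
    def test_minimal_fixture(self):
        hier, motion = parse_bvh(MINIMAL_BVH)
        assert hier.joint_names() == ["Hips", "Chest"]
        assert len(hier.joints(include_end_sites=True)) == 3  # + end site
        assert hier.n_channels == 9
        assert motion.n_frames == 2
        assert motion.frame_time == pytest.approx(0.033333)
        np.testing.assert_allclose(motion.channel_values[0, :3], [1, 2, 3])

    def test_frame_count_mismatch_reported(self):
        bad = MINIMAL_BVH.replace("Frames: 2", "Frames: 3")
        with pytest.raises(BVHParseError, match="Frames: 3"):
            parse_bvh(bad)

    def test_trailing_rows_rejected(self):
        bad = MINIMAL_BVH.replace("Frames: 2", "Frames: 1")
        with pytest.raises(BVHParseError, match="trailing"):
            parse_bvh(bad)

    def test_unknown_channel_has_line_number(self):
        bad = MINIMAL_BVH.replace("Zrotation Xrotation Yrotation\n\t\tEnd",
                                  "Zrotation Wrotation Yrotation\n\t\tEnd")
        with pytest.raises(BVHParseError, match=r"line \d+.*Wrotation"):
            parse_bvh(bad)

    def test_missing_motion_section(self):
        with pytest.raises(BVHParseError):
            parse_bvh(MINIMAL_BVH.split("MOTION")[0])

    @pytest.mark.parametrize("order", ["Zrotation Xrotation Yrotation",
                                       "Xrotation Yrotation Zrotation"])
    def test_channel_order_respected(self, order):
        text = MINIMAL_BVH.replace("CHANNELS 3 Zrotation Xrotation Yrotation",
                                   f"CHANNELS 3 {order}")
        hier, _ = parse_bvh(text)
        assert hier.joints()[1].channels == tuple(order.split())


class TestWriting:
    def test_round_trip(self):
        hier, motion = parse_bvh(MINIMAL_BVH)
        hier2, motion2 = parse_bvh(format_bvh(hier, motion))
        assert hier2.joint_names() == hier.joint_names()
        np.testing.assert_allclose(
            motion2.channel_values, motion.channel_values, atol=1e-6
        )
        assert motion2.frame_time == motion.frame_time

    def test_file_round_trip(self, tmp_path):
        hier, motion = parse_bvh(MINIMAL_BVH)
        path = tmp_path / "clip.bvh"
        write_bvh(hier, motion, path)
        hier2, motion2 = read_bvh(path)
        np.testing.assert_allclose(motion2.channel_values, motion.channel_values, atol=1e-6)

    def test_channel_count_mismatch(self):
        hier, motion = parse_bvh(MINIMAL_BVH)
        bad = MotionSequence(frame_time=0.01, channel_values=np.zeros((2, 5)))
        with pytest.raises(DimensionMismatchError):
            format_bvh(hier, bad)

    def test_empty_motion_rejected(self):
        with pytest.raises(ValueError):
            MotionSequence(frame_time=0.01, channel_values=np.zeros((0, 9)))


class TestForwardKinematics:
    def test_zero_rotations_cumulative_offsets(self):
        hier, _ = parse_bvh(MINIMAL_BVH)
        motion = MotionSequence(frame_time=0.01, channel_values=np.zeros((3, 9)))
        poses = forward_kinematics(hier, motion)
        np.testing.assert_allclose(poses.positions[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(poses.positions[:, 1], [[0, 10, 0]] * 3, atol=1e-12)

    def test_single_bone_z_rotation(self):
        hier = two_joint_hierarchy(offset=(1.0, 0.0, 0.0))
        vals = np.zeros((1, 9))
        vals[0, 3] = 90.0  # root Z rotation
        poses = forward_kinematics(hier, MotionSequence(0.01, vals))
        np.testing.assert_allclose(poses.positions[0, 1], [0.0, 1.0, 0.0], atol=1e-9)

    def test_root_translation_shifts_all_joints(self):
        hier, _ = parse_bvh(MINIMAL_BVH)
        vals = np.zeros((2, 9))
        poses0 = forward_kinematics(hier, MotionSequence(0.01, vals))
        vals2 = vals.copy()
        vals2[:, 0] = 5.0
        poses1 = forward_kinematics(hier, MotionSequence(0.01, vals2))
        np.testing.assert_array_equal(
            poses1.positions - poses0.positions,
            np.broadcast_to([5.0, 0.0, 0.0], poses0.positions.shape),
        )

    def test_extra_root_rotation_is_global_rotation(self, rng):
        # composing a fixed rotation in front of the root rotates all world
        # positions by exactly that rotation
        from scipy.spatial.transform import Rotation

        cfg = GeneratorConfig(frame_rate=30.0, duration_range=(0.5, 0.5), seed=3)
        hier, motion = generate_record(0, 0, cfg, 0)
        base = forward_kinematics(hier, motion)

        extra = 37.0  # degrees about Z; root's first rotation channel is Zrotation
        vals = motion.channel_values.copy()
        # root channels: 3 translations then Z X Y rotations; zero the root
        # translation so rotation about the origin is exact
        vals[:, :3] = 0.0
        base_nt = forward_kinematics(hier, MotionSequence(motion.frame_time, vals))
        vals_rot = vals.copy()
        rot_z = Rotation.from_euler("Z", extra, degrees=True)
        for t in range(vals.shape[0]):
            r_orig = Rotation.from_euler("ZXY", vals[t, 3:6], degrees=True)
            composed = rot_z * r_orig
            vals_rot[t, 3:6] = composed.as_euler("ZXY", degrees=True)
        rotated = forward_kinematics(hier, MotionSequence(motion.frame_time, vals_rot))
        expected = base_nt.positions @ rot_z.as_matrix().T
        np.testing.assert_allclose(rotated.positions, expected, atol=1e-9)


class TestNormalization:
    @pytest.fixture
    def poses(self, rng):
        return PoseSequence(
            positions=rng.normal(size=(4, 3, 3)), joint_names=["Hips", "A", "B"],
            frame_time=0.01,
        )

    def test_root_at_origin(self, poses):
        out = hip_normalize(poses, "Hips")
        np.testing.assert_array_equal(out.positions[:, 0], 0.0)

    def test_inter_joint_vectors_unchanged(self, poses):
        out = hip_normalize(poses)
        np.testing.assert_allclose(
            out.positions[:, 1] - out.positions[:, 2],
            poses.positions[:, 1] - poses.positions[:, 2],
            atol=1e-12,
        )

    def test_idempotent(self, poses):
        once = hip_normalize(poses)
        twice = hip_normalize(once)
        np.testing.assert_array_equal(once.positions, twice.positions)

    def test_unknown_joint(self, poses):
        with pytest.raises(KeyError, match="Pelvis"):
            hip_normalize(poses, "Pelvis")


class TestFlatten:
    def test_concatenation_order(self):
        poses = PoseSequence(
            positions=[[[1, 2, 3], [4, 5, 6]]], joint_names=["a", "b"], frame_time=0.1
        )
        flat = flatten_poses(poses)
        np.testing.assert_array_equal(flat, [[1, 2, 3, 4, 5, 6]])
        assert flat.shape == (1, 6)

    def test_unflatten_inverse(self, rng):
        poses = PoseSequence(
            positions=rng.normal(size=(5, 4, 3)), joint_names=list("abcd"), frame_time=0.1
        )
        back = unflatten_poses(flatten_poses(poses), poses.joint_names, 0.1)
        np.testing.assert_array_equal(back.positions, poses.positions)


def test_poses_csv_export(tmp_path, rng):
    import pandas as pd

    poses = PoseSequence(
        positions=rng.normal(size=(2, 3, 3)), joint_names=["Hips", "A", "B"], frame_time=0.1
    )
    path = tmp_path / "poses.csv"
    poses_to_csv(poses, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["frame", "joint", "x", "y", "z"]
    assert len(df) == 6
    row = df[(df.frame == 1) & (df.joint == "B")].iloc[0]
    np.testing.assert_allclose([row.x, row.y, row.z], poses.positions[1, 2])
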