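import numpy as np
import pytest

from ehecco import (
    GeneratorConfig,
    flatten_poses,
    forward_kinematics,
    generate_coupled_pair_dataset,
    generate_dataset,
    generate_record,
    hip_normalize,
    make_skeleton,
)
from ehecco.errors import DegenerateDataWarning
from ehecco.mocap import format_bvh, parse_bvh
from ehecco.synthetic import (
    STYLE_LINKED_COVARIATE,
    arm_channel_masks,
    record_channel_params,
    root_drift,
    subject_style,
)

FAST = dict(frame_rate=30.0, duration_range=(1.0, 2.0))


class TestSkeleton:
    def test_template_shape(self):
        hier = make_skeleton(15)
        joints = hier.joints()
        assert len(joints) == 15
        assert joints[0].name == "Hips" and len(joints[0].channels) == 6
        assert hier.n_channels == 6 + 3 * 14

    def test_extra_joints_extend_spine(self):
        hier = make_skeleton(17)
        assert len(hier.joints()) == 17
        assert "SpineExtra1" in hier.joint_names()

    def test_small_count_falls_back_to_chain(self):
        with pytest.warns(DegenerateDataWarning):
            hier = make_skeleton(5)
        assert len(hier.joints()) == 5
        assert hier.n_channels == 6 + 3 * 4

    def test_deterministic(self):
        a, b = make_skeleton(15), make_skeleton(15)
        assert a.joint_names() == b.joint_names()
        for ja, jb in zip(a.joints(True), b.joints(True)):
            np.testing.assert_array_equal(ja.offset, jb.offset)


class TestGenerateRecord:
    def test_same_key_same_record(self):
        cfg = GeneratorConfig(seed=5, **FAST)
        _, m1 = generate_record(1, 0, cfg, 2)
        _, m2 = generate_record(1, 0, cfg, 2)
        np.testing.assert_array_equal(m1.channel_values, m2.channel_values)

    def test_noiseless_channels_match_closed_form(self):
        cfg = GeneratorConfig(seed=2, noise_sd=0.0, **FAST)
        hier, motion = generate_record(2, 1, cfg, 0)
        n_rot = 3 * 15
        p = record_channel_params(2, 1, cfg, n_rot)
        t = np.arange(motion.n_frames) / cfg.frame_rate
        expected = (
            p["offset"][None, :]
            + p["sway_amplitude"] * p["sway_direction"][None, :]
            * np.sin(2 * np.pi * p["sway_frequency"] * t)[:, None]
            + p["amplitude"][None, :]
            * np.sin(2 * np.pi * p["frequency"] * t[:, None] + p["phase"][None, :])
        )
        # rotation channels: root cols 3:6, then 3 per joint
        rot_cols = list(range(3, motion.channel_values.shape[1]))
        np.testing.assert_allclose(motion.channel_values[:, rot_cols], expected, atol=1e-12)
        np.testing.assert_allclose(motion.channel_values[:, :3], root_drift(t), atol=1e-12)

    def test_all_variation_off_records_identical_up_to_duration(self):
        cfg = GeneratorConfig(
            seed=3, class_separation=0.0, style_scale=0.0, noise_sd=0.0, **FAST
        )
        _, m1 = generate_record(0, 0, cfg, 0)
        _, m2 = generate_record(2, 1, cfg, 1)
        n = min(m1.n_frames, m2.n_frames)
        np.testing.assert_array_equal(m1.channel_values[:n], m2.channel_values[:n])

    def test_id_validation(self):
        cfg = GeneratorConfig(**FAST)
        with pytest.raises(ValueError, match="class_id"):
            generate_record(9, 0, cfg, 0)


class TestGenerateDataset:
    def test_record_count_and_reproducibility(self):
        cfg = GeneratorConfig(n_classes=2, n_subjects=3, reps_per_cell=2, seed=4, **FAST)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert len(a.records) == 12
        assert len(a.labels) == len(a.subject_ids) == 12
        for (_, ma), (_, mb) in zip(a.records, b.records):
            np.testing.assert_array_equal(ma.channel_values, mb.channel_values)
        assert a.covariates.equals(b.covariates)

    def test_style_linked_covariate_correlation(self):
        cfg = GeneratorConfig(n_subjects=17, seed=0, **FAST)
        styles = np.array([subject_style(u, cfg) for u in range(17)])
        ds = generate_dataset(
            GeneratorConfig(n_classes=1, n_subjects=17, reps_per_cell=1, seed=0, **FAST)
        )
        r = np.corrcoef(styles, ds.covariates[STYLE_LINKED_COVARIATE])[0, 1]
        assert abs(r) >= 0.9

    def test_generated_bvh_reparses_losslessly(self):
        cfg = GeneratorConfig(n_classes=1, n_subjects=1, reps_per_cell=2, seed=6, **FAST)
        for hier, motion in generate_dataset(cfg).records:
            hier2, motion2 = parse_bvh(format_bvh(hier, motion))
            assert hier2.joint_names() == hier.joint_names()
            np.testing.assert_allclose(
                motion2.channel_values, motion.channel_values, atol=1e-6
            )

    def test_write_layout(self, tmp_path):
        import pandas as pd

        cfg = GeneratorConfig(n_classes=2, n_subjects=1, reps_per_cell=1, seed=0, **FAST)
        generate_dataset(cfg).write(tmp_path)
        labels = pd.read_csv(tmp_path / "labels.csv")
        assert set(labels.columns) == {"record", "class", "subject"}
        assert (tmp_path / labels.record[0]).exists()
        assert (tmp_path / "covariates.csv").exists()


def mean_poses(dataset):
    out = []
    for hier, motion in dataset.records:
        frames = flatten_poses(hip_normalize(forward_kinematics(hier, motion)))
        out.append(frames.mean(axis=0))
    return np.vstack(out)


def test_class_signal_supports_nearest_neighbor(small_synth):
    # 1-NN on flattened mean poses must already beat chance at the default
    # class separation: the recognition task is solvable before the metric
    X = mean_poses(small_synth)
    y = np.asarray(small_synth.labels)
    correct = 0
    for i in range(len(y)):
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        correct += int(y[np.argmin(d)] == y[i])
    assert correct / len(y) > 1.0 / len(np.unique(y))


@pytest.fixture(scope="module")
def pair():
    cfg = GeneratorConfig(
        n_classes=2, n_subjects=1, reps_per_cell=3, seed=1, noise_sd=0.0,
        frame_rate=30.0, duration_range=(5.0, 5.0),
    )
    return generate_coupled_pair_dataset(cfg)


class TestCoupledPair:
    def test_marginals_match_coupling_differs(self, pair):
        hier = pair.records[0][0]
        left, right = arm_channel_masks(hier)
        rot = [c for c, ch in enumerate(self._channels(hier)) if ch.endswith("rotation")]
        m0 = pair.records[0][1].channel_values[:, rot]
        m1 = pair.records[3][1].channel_values[:, rot]
        # per-channel marginal moments agree between classes
        np.testing.assert_allclose(m0.mean(axis=0), m1.mean(axis=0), atol=0.5)
        np.testing.assert_allclose(m0.std(axis=0), m1.std(axis=0), atol=0.5)
        # left-right coupling flips sign: correlate mirrored channel pairs
        li, ri = np.flatnonzero(left), np.flatnonzero(right)
        c0 = np.mean([np.corrcoef(m0[:, a], m0[:, b])[0, 1] for a, b in zip(li, ri)])
        c1 = np.mean([np.corrcoef(m1[:, a], m1[:, b])[0, 1] for a, b in zip(li, ri)])
        assert c0 > 0.9 and c1 < -0.9

    @staticmethod
    def _channels(hier):
        chans = []
        for j in hier.joints(include_end_sites=True):
            chans.extend(j.channels)
        return chans

    def test_requires_two_classes(self):
        with pytest.raises(ValueError, match="two-class"):
            generate_coupled_pair_dataset(GeneratorConfig(n_classes=3))
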