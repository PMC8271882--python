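"""Synthetic articulated-skeleton motion with known ground truth.

The generator emulates labeled, multi-class, multi-subject Mocap data: a
fixed humanoid-like skeleton whose rotation channels follow sums of
sinusoids with closed-form parameters, so every record has an analytic
ground truth. Variation is layered:

- a *shared postural sway*: one large, slow sinusoidal factor common to all
  records (it dominates pose variance, mimicking the low-dimensional
  structure of real movement);
- a *class component*: per-class offsets, amplitudes, phases and a class
  frequency, all displaced from common base values proportionally to
  ``class_separation`` (0 removes all class differences);
- a *subject style*: a scalar style draw per subject shifting channel
  offsets along a fixed direction, scaled by ``style_scale`` (posture
  differences between individuals, class-independent);
- per-frame Gaussian jitter of ``noise_sd`` degrees on rotation channels.

Record durations are drawn uniformly from ``duration_range`` so time-series
lengths vary. The root carries a deterministic slow translation drift, so
hip normalization is always exercised. Seeds are hierarchical (master seed
-> per-class / per-subject / per-record streams): subsetting a dataset
never changes the surviving records.

Each subject also gets a covariate table row: one size-like column with a
known linear dependence on the hidden style scalar, plus independent
Gaussian distractor columns — the fixture for the correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateDataWarning
from .mocap import Joint, MotionSequence, SkeletonHierarchy

# fixed kinematic constants of the motion model (degrees, Hz)
SWAY_AMPLITUDE = 20.0
SWAY_FREQUENCY = 0.4
BASE_FREQUENCY = 1.0
CLASS_OFFSET_SD = 8.0
CLASS_AMPLITUDE_SD = 3.0
CLASS_PHASE_SD = 0.7
CLASS_FREQUENCY_SD = 0.25
STYLE_OFFSET_SCALE = 3.0
#: covariate model: size_like = COV_SLOPE * style + COV_INTERCEPT + noise
COV_SLOPE = 9.0
COV_INTERCEPT = 170.0
COV_NOISE_SD = 1.2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_classes: int = 5
    n_subjects: int = 4
    reps_per_cell: int = 5
    n_joints: int = 15
    frame_rate: float = 120.0
    duration_range: tuple[float, float] = (2.0, 4.0)
    class_separation: float = 1.0
    style_scale: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.n_subjects, self.reps_per_cell) < 1:
            raise ValueError("counts must be >= 1")
        if self.class_separation < 0 or self.style_scale < 0 or self.noise_sd < 0:
            raise ValueError("scales must be >= 0")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid duration_range {self.duration_range}")

    @property
    def n_records(self) -> int:
        return self.n_classes * self.n_subjects * self.reps_per_cell


def correlation_study_config(seed: int = 0) -> GeneratorConfig:
    """Conditions for the anthropometric-correlation study.

    17 subjects (the cohort size of interest), two action classes, three
    repetitions, and a strong style scale so subject posture — not action —
    drives the between-record geometry: the analysis asks whether a
    size-like covariate can be read off the learned representation.
    """
    return GeneratorConfig(
        n_classes=2, n_subjects=17, reps_per_cell=3, style_scale=4.0, seed=seed
    )


@dataclass
class SyntheticDataset:
    """Generated records with labels, subjects, covariates and hidden truth."""

    records: list[tuple[SkeletonHierarchy, MotionSequence]]
    labels: np.ndarray
    subject_ids: np.ndarray
    covariates: pd.DataFrame  # indexed by subject_id
    styles: np.ndarray  # hidden per-subject style scalar (ground truth)
    config: GeneratorConfig

    def write(self, directory) -> None:
        """BVH files plus labels.csv and covariates.csv."""
        import os

        from .mocap import write_bvh

        os.makedirs(directory, exist_ok=True)
        rows = []
        for i, ((hier, motion), label, subj) in enumerate(
            zip(self.records, self.labels, self.subject_ids)
        ):
            name = f"record_{i:04d}.bvh"
            write_bvh(hier, motion, os.path.join(directory, name))
            rows.append({"record": name, "class": int(label), "subject": int(subj)})
        pd.DataFrame(rows).to_csv(os.path.join(directory, "labels.csv"), index=False)
        self.covariates.to_csv(os.path.join(directory, "covariates.csv"))


# ---------------------------------------------------------------------------
# skeleton template


def _chain(names_offsets: list[tuple[str, tuple[float, float, float]]], end_offset) -> Joint:
    name, off = names_offsets[0]
    j = Joint(name=name, offset=off, channels=("Zrotation", "Xrotation", "Yrotation"))
    if len(names_offsets) > 1:
        j.children.append(_chain(names_offsets[1:], end_offset))
    else:
        j.children.append(Joint(name=f"__end_{name}", offset=end_offset, is_end_site=True))
    return j


def make_skeleton(n_joints: int = 15) -> SkeletonHierarchy:
    """Deterministic humanoid-like tree (root/hip, spine+head, arms, legs).

    The template uses 15 articulated joints; larger counts extend the spine
    chain. Counts below 15 fall back to a simple kinematic chain with a
    warning. The root carries 6 channels, every other joint 3 rotations.
    """
    if n_joints < 2:
        raise ValueError(f"need at least 2 joints, got {n_joints}")
    rot = ("Zrotation", "Xrotation", "Yrotation")
    if n_joints < 15:
        warnings.warn(
            f"n_joints={n_joints} is too small for the humanoid template; "
            "using a simple chain",
            DegenerateDataWarning,
            stacklevel=2,
        )
        root = Joint(
            name="Hips",
            offset=(0.0, 0.0, 0.0),
            channels=("Xposition", "Yposition", "Zposition") + rot,
        )
        cur = root
        for k in range(1, n_joints):
            nxt = Joint(name=f"Link{k}", offset=(0.0, 10.0, 0.0), channels=rot)
            cur.children.append(nxt)
            cur = nxt
        cur.children.append(Joint(name="__end_chain", offset=(0.0, 10.0, 0.0), is_end_site=True))
        return SkeletonHierarchy(root=root)

    n_extra = n_joints - 15
    spine = [("Spine", (0.0, 12.0, 0.0))]
    spine += [(f"SpineExtra{k}", (0.0, 4.0, 0.0)) for k in range(1, n_extra + 1)]
    spine += [("Chest", (0.0, 14.0, 0.0))]

    head = _chain([("Neck", (0.0, 12.0, 0.0)), ("Head", (0.0, 10.0, 0.0))], (0.0, 8.0, 0.0))
    left_arm = _chain(
        [
            ("LeftShoulder", (-17.0, 9.0, 0.0)),
            ("LeftElbow", (-28.0, 0.0, 0.0)),
            ("LeftHand", (-25.0, 0.0, 0.0)),
        ],
        (-9.0, 0.0, 0.0),
    )
    right_arm = _chain(
        [
            ("RightShoulder", (17.0, 9.0, 0.0)),
            ("RightElbow", (28.0, 0.0, 0.0)),
            ("RightHand", (25.0, 0.0, 0.0)),
        ],
        (9.0, 0.0, 0.0),
    )
    left_leg = _chain(
        [("LeftUpLeg", (-9.0, -4.0, 0.0)), ("LeftFoot", (0.0, -80.0, 0.0))], (0.0, -8.0, 14.0)
    )
    right_leg = _chain(
        [("RightUpLeg", (9.0, -4.0, 0.0)), ("RightFoot", (0.0, -80.0, 0.0))], (0.0, -8.0, 14.0)
    )

    chest_children = [head, left_arm, right_arm]
    torso: Joint | None = None
    for name, off in reversed(spine):
        j = Joint(name=name, offset=off, channels=rot)
        j.children = chest_children if torso is None else [torso]
        torso = j
    root = Joint(
        name="Hips",
        offset=(0.0, 0.0, 0.0),
        channels=("Xposition", "Yposition", "Zposition") + rot,
    )
    root.children = [torso, left_leg, right_leg]
    return SkeletonHierarchy(root=root)


# ---------------------------------------------------------------------------
# motion parameters


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _n_rotation_channels(hierarchy: SkeletonHierarchy) -> int:
    return sum(
        sum(ch.endswith("rotation") for ch in j.channels) for j in hierarchy.joints()
    )


def base_channel_params(config: GeneratorConfig, n_rot: int) -> dict[str, np.ndarray]:
    """Seed-determined base values shared by every class and subject."""
    rng = _rng(config.seed, 0)
    return {
        "offset": rng.uniform(-25.0, 25.0, n_rot),
        "amplitude": rng.uniform(4.0, 9.0, n_rot),
        "phase": rng.uniform(0.0, 2.0 * np.pi, n_rot),
        "sway_direction": rng.normal(0.0, 1.0, n_rot),
        "style_direction": rng.normal(0.0, 1.0, n_rot),
    }


def subject_style(subject_id: int, config: GeneratorConfig) -> float:
    """Hidden per-subject style scalar (standard normal draw)."""
    return float(_rng(config.seed, 2, subject_id).normal())


def record_channel_params(
    class_id: int, subject_id: int, config: GeneratorConfig, n_rot: int
) -> dict[str, np.ndarray | float]:
    """Closed-form sinusoid parameters for every rotation channel.

    Channel r of a record from (class c, subject u) follows

        theta_r(t) = offset_r + A_sway * w_r * sin(2 pi f_sway t)
                     + A_r * sin(2 pi f_c t + phi_r) + noise,

    where offsets include the class displacement (scaled by
    ``class_separation``) and the subject style shift (scaled by
    ``style_scale``).
    """
    base = base_channel_params(config, n_rot)
    crng = _rng(config.seed, 1, class_id)
    sep = config.class_separation
    d_off = crng.normal(0.0, CLASS_OFFSET_SD, n_rot)
    d_amp = crng.normal(0.0, CLASS_AMPLITUDE_SD, n_rot)
    d_phase = crng.normal(0.0, CLASS_PHASE_SD, n_rot)
    d_freq = crng.normal(0.0, CLASS_FREQUENCY_SD)
    style = subject_style(subject_id, config)
    return {
        "offset": base["offset"]
        + sep * d_off
        + config.style_scale * style * STYLE_OFFSET_SCALE * base["style_direction"],
        "amplitude": np.abs(base["amplitude"] + sep * d_amp),
        "phase": base["phase"] + sep * d_phase,
        "frequency": max(0.2, BASE_FREQUENCY + sep * d_freq),
        "sway_amplitude": SWAY_AMPLITUDE,
        "sway_frequency": SWAY_FREQUENCY,
        "sway_direction": base["sway_direction"],
    }


def root_drift(t: np.ndarray) -> np.ndarray:
    """Deterministic slow root translation (T, 3): exercised by hip normalization."""
    return np.stack(
        [2.0 * np.sin(2.0 * np.pi * 0.3 * t), 1.0 * np.sin(2.0 * np.pi * 0.4 * t + 1.0), 4.0 * t],
        axis=1,
    )


def generate_record(
    class_id: int,
    subject_id: int,
    config: GeneratorConfig,
    record_seed: int | tuple[int, ...] = (),
    *,
    hierarchy: SkeletonHierarchy | None = None,
    params_transform=None,
) -> tuple[SkeletonHierarchy, MotionSequence]:
    """One synthetic record; same (class, subject, record_seed) => identical output.

    ``params_transform``, if given, maps the channel-parameter dict to a
    modified copy before synthesis — used by the coupled-pair fixture to
    rewrite limb phases.
    """
    if not 0 <= class_id < config.n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {config.n_classes})")
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError(f"subject_id {subject_id} outside [0, {config.n_subjects})")
    if hierarchy is None:
        hierarchy = make_skeleton(config.n_joints)
    n_rot = _n_rotation_channels(hierarchy)
    params = record_channel_params(class_id, subject_id, config, n_rot)
    if params_transform is not None:
        params = params_transform(dict(params))

    key = record_seed if isinstance(record_seed, tuple) else (int(record_seed),)
    rrng = _rng(config.seed, 3, class_id, subject_id, *key)
    duration = rrng.uniform(*config.duration_range)
    n_frames = max(2, int(round(duration * config.frame_rate)))
    t = np.arange(n_frames) / config.frame_rate

    phase = np.asarray(params["phase"], dtype=float)
    angles = (
        params["offset"][None, :]
        + params["sway_amplitude"]
        * params["sway_direction"][None, :]
        * np.sin(2.0 * np.pi * params["sway_frequency"] * t)[:, None]
        + params["amplitude"][None, :]
        * np.sin(2.0 * np.pi * params["frequency"] * t[:, None] + phase[None, :])
    )
    if config.noise_sd > 0:
        angles = angles + rrng.normal(0.0, config.noise_sd, angles.shape)

    # assemble the full channel matrix in hierarchy order
    values = np.empty((n_frames, hierarchy.n_channels))
    drift = root_drift(t)
    col = 0
    rot_col = 0
    for j in hierarchy.joints(include_end_sites=True):
        for ch in j.channels:
            if ch.endswith("position"):
                values[:, col] = drift[:, "XYZ".index(ch[0])]
            else:
                values[:, col] = angles[:, rot_col]
                rot_col += 1
            col += 1
    motion = MotionSequence(frame_time=1.0 / config.frame_rate, channel_values=values)
    return hierarchy, motion


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full factorial classes x subjects x repetitions, plus covariates."""
    hierarchy = make_skeleton(config.n_joints)
    records, labels, subjects = [], [], []
    for c in range(config.n_classes):
        for u in range(config.n_subjects):
            for rep in range(config.reps_per_cell):
                records.append(
                    generate_record(c, u, config, (rep,), hierarchy=hierarchy)
                )
                labels.append(c)
                subjects.append(u)
    styles = np.array([subject_style(u, config) for u in range(config.n_subjects)])
    covariates = _make_covariates(styles, config)
    return SyntheticDataset(
        records=records,
        labels=np.asarray(labels),
        subject_ids=np.asarray(subjects),
        covariates=covariates,
        styles=styles,
        config=config,
    )


def _make_covariates(styles: np.ndarray, config: GeneratorConfig) -> pd.DataFrame:
    """Size-like column linear in style, plus independent distractors."""
    rng = _rng(config.seed, 4)
    n = len(styles)
    df = pd.DataFrame(
        {
            "height_cm": COV_INTERCEPT + COV_SLOPE * styles + rng.normal(0, COV_NOISE_SD, n),
            "age_years": rng.normal(24.0, 4.0, n),
            "sitting_height_cm": rng.normal(90.0, 4.0, n),
            "thigh_perimeter_cm": rng.normal(54.0, 4.0, n),
            "triceps_skinfold_mm": rng.normal(11.0, 3.0, n),
        },
        index=pd.Index(np.arange(n), name="subject"),
    )
    return df


#: covariate column with known linear style dependence
STYLE_LINKED_COVARIATE = "height_cm"
DISTRACTOR_COVARIATES = (
    "age_years",
    "sitting_height_cm",
    "thigh_perimeter_cm",
    "triceps_skinfold_mm",
)


def arm_channel_masks(hierarchy: SkeletonHierarchy) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over rotation channels for left- and right-arm joints."""
    left = np.zeros(_n_rotation_channels(hierarchy), dtype=bool)
    right = np.zeros_like(left)
    rot_col = 0
    for j in hierarchy.joints():
        n_rot = sum(ch.endswith("rotation") for ch in j.channels)
        sl = slice(rot_col, rot_col + n_rot)
        if j.name.startswith("Left") and ("Shoulder" in j.name or "Elbow" in j.name or "Hand" in j.name):
            left[sl] = True
        if j.name.startswith("Right") and ("Shoulder" in j.name or "Elbow" in j.name or "Hand" in j.name):
            right[sl] = True
        rot_col += n_rot
    return left, right


def generate_coupled_pair_dataset(
    config: GeneratorConfig | None = None,
) -> SyntheticDataset:
    """Two classes with matching per-channel marginals, differing only in
    inter-limb phase coupling.

    Right-arm channel parameters are rewritten to mirror the left-arm ones,
    so in class 0 the two arms move exactly in phase; class 1 adds pi to
    every right-arm phase (anti-phase). Each channel's marginal amplitude
    distribution is unchanged between classes, while the joint left-right
    dependence flips sign — only a joint-distribution metric can tell the
    classes apart.
    """
    if config is None:
        config = GeneratorConfig(n_classes=2, class_separation=0.0)
    if config.n_classes != 2:
        raise ValueError("the coupled-pair fixture is a two-class design")
    if config.n_joints != 15:
        raise ValueError("the coupled-pair fixture requires the 15-joint template")
    cfg = replace(config, class_separation=0.0)
    hierarchy = make_skeleton(cfg.n_joints)
    left, right = arm_channel_masks(hierarchy)

    def mirror(anti_phase: bool):
        def transform(params: dict) -> dict:
            for key in ("offset", "amplitude", "phase"):
                arr = np.array(params[key], dtype=float, copy=True)
                arr[right] = arr[left]
                if key == "phase" and anti_phase:
                    arr[right] += np.pi
                params[key] = arr
            sway = np.array(params["sway_direction"], dtype=float, copy=True)
            # sign flip = half-period phase shift; the (symmetric) marginal
            # of each channel is unchanged
            sway[right] = -sway[left] if anti_phase else sway[left]
            params["sway_direction"] = sway
            return params

        return transform

    records, labels, subjects = [], [], []
    for c in range(2):
        transform = mirror(anti_phase=(c == 1))
        for u in range(cfg.n_subjects):
            for rep in range(cfg.reps_per_cell):
                records.append(
                    generate_record(
                        0, u, cfg, (c, rep), hierarchy=hierarchy, params_transform=transform
                    )
                )
                labels.append(c)
                subjects.append(u)
    styles = np.array([subject_style(u, cfg) for u in range(cfg.n_subjects)])
    return SyntheticDataset(
        records=records,
        labels=np.asarray(labels),
        subject_ids=np.asarray(subjects),
        covariates=_make_covariates(styles, cfg),
        styles=styles,
        config=cfg,
    )
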