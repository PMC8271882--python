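"""BVH round trip, forward kinematics and pose codebooks.

Writes a generated record to BVH text, reads it back, reconstructs world
joint positions by forward kinematics, hip-normalizes them and selects a
codebook of representative poses by spectral clustering.
"""

import tempfile
from pathlib import Path

import numpy as np

from ehecco import (
    GeneratorConfig,
    build_codebook,
    flatten_poses,
    forward_kinematics,
    generate_record,
    hip_normalize,
    read_bvh,
    write_bvh,
)

cfg = GeneratorConfig(frame_rate=60.0, duration_range=(2.0, 2.0), seed=0)
hier, motion = generate_record(class_id=0, subject_id=0, config=cfg, record_seed=0)
print(f"skeleton: {len(hier.joints())} joints, {hier.n_channels} channels; "
      f"{motion.n_frames} frames at {1 / motion.frame_time:.0f} Hz")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "record.bvh"
    write_bvh(hier, motion, path)
    hier2, motion2 = read_bvh(path)
err = np.abs(
    forward_kinematics(hier2, motion2).positions
    - forward_kinematics(hier, motion).positions
).max()
print(f"BVH round-trip worst-case world-position error: {err:.2e} length units")

poses = hip_normalize(forward_kinematics(hier, motion))
print(f"after hip normalization the root stays at "
      f"{np.abs(poses.positions[:, 0]).max():.1f} in every frame")

frames = flatten_poses(poses)
cb = build_codebook(frames, n_clusters=12, seed=0)
span = (cb.indices.max() - cb.indices.min()) / (frames.shape[0] - 1)
print(f"codebook: {cb.n_clusters} representative poses at frames {cb.indices.tolist()}")
print(f"temporal coverage: {100 * span:.0f}% of the record")
print("\nEvery codebook pose is an actual recorded frame (cluster medoid),")
print("and the indices spread over the whole record, so the summary keeps")
print("the cyclic structure of the movement.")
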