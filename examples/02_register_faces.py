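"""Register face frames to an iteratively refined reference.

Runs the dense gradient-based registration on a small clip set: builds the
average-texture reference (3 update iterations), registers every frame, and
reports the residual improvement and the 5-channel representation size.
"""

import numpy as np

from facevalence import pipeline
from facevalence.synthetic import DatasetSpec, ExpressionParams

spec = DatasetSpec(
    n_subjects=1, phrases_per_class=2, repeats_per_subject=(2,),
    clip_types=("prefix",), n_frames_prefix=8, image_size=64,
    valence_effect=ExpressionParams(head_dy=6, mouth_curve=0.9), seed=5)

data = pipeline.build_registered_dataset(spec)

print(f"reference built from {sum(c.n_frames for c in data.clips)} frames; "
      f"per-iteration change norms: "
      f"{np.round(data.reference.change_norms, 4).tolist()}")
print(f"registered stack: {data.stack.shape} "
      f"(dx, dy, warped R, G, B per pixel)")
print(f"flattened sample length: {data.samples.shape[1]}")

ref = data.reference.image
frame = data.clips[0].frames[-1]
warped = data.stack[data.clips[0].n_frames - 1, ..., 2:]
before = np.sqrt(np.mean((frame - ref) ** 2))
after = np.sqrt(np.mean((warped - ref) ** 2))
print(f"\nframe-to-reference RMSE: {before:.4f} raw -> {after:.4f} after "
      "warping -> the warp absorbs the expression/pose change, leaving a "
      "'shape-free' texture.")
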