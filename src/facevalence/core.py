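"""Shared container types for clips and their metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALENCE_CLASSES = ("positive", "negative")
CLIP_TYPES = ("prefix", "suffix")


@dataclass(frozen=True)
class ClipMetadata:
    """Identity of a single clip within a recording design.

    The tuple (subject, phrase, valence class, repeat, clip type) uniquely
    identifies a clip: each subject delivers every phrase of each class a fixed
    number of times, and each delivery is cut into a fixed-length opening
    ("prefix") segment and a variable-length remainder ("suffix") segment.
    """

    subject_id: str
    phrase_id: int
    valence_class: str
    repeat_index: int
    clip_type: str
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.valence_class not in VALENCE_CLASSES:
            raise ValueError(f"valence_class must be one of {VALENCE_CLASSES}, "
                             f"got {self.valence_class!r}")
        if self.clip_type not in CLIP_TYPES:
            raise ValueError(f"clip_type must be one of {CLIP_TYPES}, "
                             f"got {self.clip_type!r}")
        if self.phrase_id < 1:
            raise ValueError("phrase_id is 1-based and must be >= 1")
        if self.repeat_index < 1:
            raise ValueError("repeat_index is 1-based and must be >= 1")

    @property
    def clip_id(self) -> str:
        return (f"{self.subject_id}_{self.valence_class}"
                f"_p{self.phrase_id:02d}_r{self.repeat_index:02d}"
                f"_{self.clip_type}")


@dataclass
class Clip:
    """An ordered sequence of colour frames plus its metadata.

    ``frames`` has shape (n_frames, H, W, 3) with values in [0, 1] quantised
    to the 8-bit grid, so that lossless PNG round trips are bit-exact.
    ``latents`` optionally records the per-frame latent expression parameters
    used by the synthetic generator (n_frames, n_params); it is diagnostic
    only and is not persisted.
    """

    frames: np.ndarray
    meta: ClipMetadata
    latents: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n_frames, H, W, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_size(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]
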