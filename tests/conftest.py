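"""Shared fixtures: small synthetic datasets and a cached registered pipeline.

The image pipeline fixture is deliberately small (one subject, 4 phrases per
class, 3 repeats, 12-frame clips at 64 px) so the full register → embed →
discriminate → back-project chain runs once per session in a few seconds.
"""

import numpy as np
import pytest

from facevalence import pipeline
from facevalence.synthetic import DatasetSpec, ExpressionParams

STRONG_EFFECT = ExpressionParams(head_dy=6.0, head_pitch=6.0,
                                 mouth_curve=0.9, brow_raise=0.4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Minimal design for structural tests (no rendering needed)."""
    return DatasetSpec(n_subjects=1, phrases_per_class=2,
                       repeats_per_subject=(2,), n_frames_prefix=4,
                       suffix_frame_range=(3, 6), image_size=48, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """Small renderable design with a strong valence signal."""
    return DatasetSpec(n_subjects=1, phrases_per_class=4,
                       repeats_per_subject=(3,), clip_types=("prefix",),
                       n_frames_prefix=12, image_size=64,
                       valence_effect=STRONG_EFFECT, seed=5)


@pytest.fixture(scope="session")
def registered(small_spec):
    """Registered small dataset (reference + 5-channel stack)."""
    return pipeline.build_registered_dataset(small_spec)


@pytest.fixture(scope="session")
def discriminant(registered):
    """Full-data embedding + LDA + discriminant axis on the small dataset."""
    return pipeline.fit_full_discriminant(registered, ridge=1e-8)
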