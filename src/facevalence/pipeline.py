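"""High-level convenience wrappers chaining the pipeline stages.

These functions wire together the synthetic generator, registration, face
space, classifier and discriminant axis for the common end-to-end analyses;
all scientific content lives in the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import axis as axis_mod
from . import classify, face_space, registration
from .classify import CvResult, ZScaler
from .core import Clip
from .synthetic import DatasetSpec, generate_dataset


@dataclass
class RegisteredDataset:
    clips: list[Clip]
    manifest: pd.DataFrame
    reference: registration.ReferenceTemplate
    stack: np.ndarray          # (n, H, W, 5)
    index: pd.DataFrame        # sample -> (clip_id, frame)

    @property
    def samples(self) -> np.ndarray:
        return registration.flatten_stack(self.stack)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.stack.shape[1], self.stack.shape[2]


def build_registered_dataset(spec: DatasetSpec,
                             n_iterations: int = 3,
                             cfg: registration.WarpConfig | None = None
                             ) -> RegisteredDataset:
    """Generate the synthetic clips of ``spec`` and register them: build the
    average-texture reference (3 update iterations by default) and produce
    the 5-channel representation of every frame."""
    clips, manifest = generate_dataset(spec)
    reference, stack, index = registration.register_subject(
        clips, n_iterations=n_iterations, cfg=cfg)
    return RegisteredDataset(clips=clips, manifest=manifest,
                             reference=reference, stack=stack, index=index)


def within_subject_mcgm_cv(data: RegisteredDataset, *,
                           threshold: float = 0.90,
                           max_components: int | None = None,
                           ridge: float = 0.0,
                           zscore_mode: str = "independent") -> CvResult:
    """Leave-one-phrase-out valence classification on the registered stack,
    refitting the PCA embedding on the training frames of each fold."""
    return classify.run_within_subject_cv(
        data.samples, data.index["clip_id"].to_numpy(), data.manifest,
        use_pca=True, threshold=threshold, max_components=max_components,
        ridge=ridge, zscore_mode=zscore_mode)


@dataclass
class DiscriminantFit:
    embedding: face_space.EmbeddingModel
    scaler: ZScaler
    lda: classify.LdaModel
    axis: axis_mod.DiscriminantAxis
    coords: np.ndarray     # z-scored embedding coordinates of all samples
    labels: np.ndarray


def fit_full_discriminant(data: RegisteredDataset, *,
                          threshold: float = 0.90,
                          max_components: int | None = None,
                          ridge: float = 0.0) -> DiscriminantFit:
    """Refit embedding + LDA on the full dataset (no cross-validation) and
    extract the valence discriminant axis, as used for back-projection."""
    X = data.samples
    model = face_space.fit_embedding(X, threshold,
                                     max_components=max_components)
    coords = face_space.transform(model, X)
    scaler = ZScaler.fit(coords)
    Z = scaler.transform(coords)
    cls_of = dict(zip(data.manifest["clip_id"], data.manifest["class"]))
    y = np.array([cls_of[c] for c in data.index["clip_id"]])
    lda = classify.fit_lda(Z, y, ridge=ridge)
    ax = axis_mod.extract_axis(lda, Z, y)
    return DiscriminantFit(embedding=model, scaler=scaler, lda=lda, axis=ax,
                           coords=Z, labels=y)


def back_project_axis_images(data: RegisteredDataset, fit: DiscriminantFit,
                             range_sd: float = 3.0, step_sd: float = 0.5,
                             enhance: bool = False) -> tuple[np.ndarray, list]:
    """Images along the discriminant axis (13 under the defaults)."""
    s, pts = axis_mod.sample_axis_grid(fit.axis, range_sd, step_sd)
    images = []
    for p in pts:
        img = axis_mod.back_project(p, fit.scaler, fit.embedding,
                                    data.image_shape)
        if enhance:
            img = axis_mod.unsharp_mask(img)
        images.append(img)
    return s, images
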