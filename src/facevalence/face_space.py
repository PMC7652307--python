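"""PCA face space: linear embedding of flattened 5-channel samples.

The embedding retains the minimal number of principal components explaining a
target fraction (default 90%) of the variance across samples. Because sample
counts are always far below the 81,920-dimensional ambient space, the
decomposition is computed economy-size on the centred data matrix. For very
large sample sets a randomized solver can be requested by capping
``max_components``; explained-variance ratios are always computed against the
exact total variance, so the retained k is unaffected as long as the cap
exceeds it.

Component signs are fixed (largest-magnitude loading positive) so serialised
models are reproducible. Inside cross-validation, the embedding is fitted on
training samples only and the identical coefficients are applied to both
splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


class LeakageError(ValueError):
    """Train and test sample indices overlap."""


@dataclass
class EmbeddingModel:
    mean_: np.ndarray                 # (D,)
    components_: np.ndarray           # (m, D), orthonormal rows, m >= k
    explained_variance_: np.ndarray   # (m,)
    total_variance_: float
    k: int
    threshold: float

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self.explained_variance_ / self.total_variance_

    @property
    def retained_components_(self) -> np.ndarray:
        return self.components_[:self.k]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_embedding(samples: np.ndarray, threshold: float = 0.90,
                  max_components: int | None = None,
                  random_state: int = 0,
                  randomized_n_iter: int = 4) -> EmbeddingModel:
    """Fit the PCA embedding, retaining the minimal k whose cumulative
    explained-variance ratio reaches ``threshold``.

    Variance uses the 1/(n-1) sample normalisation. With ``max_components``
    set, a seeded randomized solver computes only the leading components; an
    error is raised if they do not reach the threshold.
    """
    X = np.asarray(samples, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("samples contain non-finite values")
    n, D = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc ** 2).sum() / (n - 1))
    if total_var <= 0:
        raise ValueError("zero total variance; embedding undefined")

    if max_components is None:
        _, S, Vt = linalg.svd(Xc, full_matrices=False)
        ev = S ** 2 / (n - 1)
        keep = ev > max(1e-12 * ev[0], 0.0)
        ev, Vt = ev[keep], Vt[keep]
    else:
        from sklearn.utils.extmath import randomized_svd
        m = min(max_components, n - 1, D)
        _, S, Vt = randomized_svd(Xc, n_components=m, n_iter=randomized_n_iter,
                                  random_state=random_state)
        ev = S ** 2 / (n - 1)

    ratios = ev / total_var
    cum = np.cumsum(ratios)
    # Smallest k with cumulative ratio >= threshold (tiny slack for exact ties).
    idx = np.searchsorted(cum, threshold - 1e-12, side="left")
    if idx >= len(cum):
        if max_components is not None:
            raise ValueError(
                f"max_components={max_components} explains only "
                f"{cum[-1]:.4f} < {threshold} of the variance; raise the cap")
        idx = len(cum) - 1
    k = int(idx + 1)
    return EmbeddingModel(mean_=mean, components_=_fix_signs(Vt),
                          explained_variance_=ev, total_variance_=total_var,
                          k=k, threshold=threshold)


def transform(model: EmbeddingModel, samples: np.ndarray) -> np.ndarray:
    X = np.asarray(samples, dtype=np.float64)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.mean_.shape[0]:
        raise ValueError(f"dimension mismatch: samples have {X.shape[1]} "
                         f"features, model expects {model.mean_.shape[0]}")
    C = (X - model.mean_) @ model.retained_components_.T
    return C[0] if squeeze else C


def inverse_transform(model: EmbeddingModel, coords: np.ndarray) -> np.ndarray:
    C = np.asarray(coords, dtype=np.float64)
    squeeze = C.ndim == 1
    C = np.atleast_2d(C)
    if C.shape[1] != model.k:
        raise ValueError(f"dimension mismatch: coords have {C.shape[1]} "
                         f"components, model retains {model.k}")
    X = model.mean_ + C @ model.retained_components_
    return X[0] if squeeze else X


def fit_cv_embedding(train_samples: np.ndarray, test_samples: np.ndarray,
                     threshold: float = 0.90,
                     train_idx=None, test_idx=None,
                     **fit_kw) -> tuple[EmbeddingModel, np.ndarray, np.ndarray]:
    """Fit on training samples only; project train and test with identical
    coefficients. If sample indices are supplied, overlap raises LeakageError.
    """
    if train_idx is not None and test_idx is not None:
        overlap = set(np.asarray(train_idx).tolist()) & \
            set(np.asarray(test_idx).tolist())
        if overlap:
            raise LeakageError(
                f"train/test sample indices overlap: {sorted(overlap)[:5]} ...")
    model = fit_embedding(train_samples, threshold, **fit_kw)
    return model, transform(model, train_samples), transform(model, test_samples)


def fit_common_embedding(per_subject_samples: list[np.ndarray],
                         threshold: float = 0.90,
                         **fit_kw) -> tuple[list[EmbeddingModel], int]:
    """Fit one embedding per subject with a shared component count.

    The shared k is the maximum over subjects of each subject's minimal k, so
    every subject's retained components explain at least the threshold
    fraction of that subject's variance.
    """
    if len(per_subject_samples) < 2:
        raise ValueError("need at least 2 subjects")
    models = [fit_embedding(X, threshold, **fit_kw) for X in per_subject_samples]
    shared_k = max(m.k for m in models)
    for m in models:
        if m.components_.shape[0] < shared_k:
            raise ValueError(
                f"a subject's decomposition holds only {m.components_.shape[0]} "
                f"components but the shared count is {shared_k}; raise "
                f"max_components or supply more samples")
        m.k = shared_k
    return models, shared_k
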