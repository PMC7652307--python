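"""The valence discriminant dimension and its back-projection to images.

After refitting the LDA to the full dataset, the discriminant dimension is the
unit direction orthogonal to the decision boundary (the normalised LDA weight
vector), with its origin on the boundary and distances measured in standard
deviations of the pooled projections of all samples. Sampling points along
this dimension and inverting, in order, the z-scoring, the PCA, and the warp
component of the 5-channel representation produces hypothetical face images
that visualise what distinguishes positive from negative valence.

Note on geometry: a line through the two class centroids is orthogonal to the
LDA boundary only when the pooled covariance is spherical. Since the
projection construction requires orthogonality to the boundary, the weight
vector defines the direction here; the centroid-difference variant is
available behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import registration
from .classify import LdaModel, ZScaler
from .face_space import EmbeddingModel, inverse_transform


class FoldOverError(RuntimeError):
    """Reconstructed warp field folds over (displacement gradient >= 1)."""

    def __init__(self, grad: float):
        super().__init__(
            f"reconstructed warp field is not invertible: max displacement "
            f"gradient {grad:.3f} >= 1")
        self.max_gradient = grad


@dataclass
class DiscriminantAxis:
    """Unit direction in (z-scored) embedding space, origin on the decision
    boundary, and the pooled-projection SD defining the axis unit."""

    direction: np.ndarray
    origin: np.ndarray
    sd: float
    positive_class: str

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Signed distance from the origin along the axis, in SD units."""
        return (np.atleast_2d(coords) - self.origin) @ self.direction / self.sd


def extract_axis(lda_model: LdaModel, coords: np.ndarray, labels,
                 positive_class: str = "positive",
                 use_centroid_direction: bool = False) -> DiscriminantAxis:
    """Extract the discriminant dimension from a full-data LDA fit.

    The direction is the normalised weight vector (orthogonal to the
    boundary), signed so the positive-valence centroid projects positively.
    The origin is the boundary point midway between the projected centroids.
    The SD is computed from the projections of all samples pooled over both
    classes (1/(n-1) normalisation).
    """
    coords = np.asarray(coords, dtype=np.float64)
    y = np.asarray(labels)
    if use_centroid_direction:
        mu_pos = coords[y == positive_class].mean(axis=0)
        mu_neg = coords[y != positive_class].mean(axis=0)
        w = mu_pos - mu_neg
    else:
        w = lda_model.weights_
    norm = float(np.linalg.norm(w))
    if norm <= 1e-15:
        raise ValueError("degenerate (zero) discriminant weight vector")
    u = w / norm

    # Point on the boundary: project the centroid midpoint onto the boundary
    # plane {x : w.x + b = 0} along the weight direction.
    mid = 0.5 * (coords[y == positive_class].mean(axis=0)
                 + coords[y != positive_class].mean(axis=0))
    wn = lda_model.weights_ / np.linalg.norm(lda_model.weights_)
    offset = (lda_model.weights_ @ mid + lda_model.intercept_) \
        / np.linalg.norm(lda_model.weights_)
    origin = mid - offset * wn

    if (coords[y == positive_class].mean(axis=0) - origin) @ u < 0:
        u = -u
    proj = (coords - origin) @ u
    sd = float(np.std(proj, ddof=1))
    return DiscriminantAxis(direction=u, origin=origin, sd=sd,
                            positive_class=positive_class)


def sample_axis_grid(axis: DiscriminantAxis, range_sd: float = 3.0,
                     step_sd: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced points origin + s * SD * direction for
    s in {-range, ..., +range} in steps of ``step_sd`` (13 points under the
    defaults). Returns (s values, embedding points)."""
    if step_sd <= 0:
        raise ValueError("step_sd must be positive")
    n = range_sd / step_sd
    if abs(n - round(n)) > 1e-9:
        raise ValueError("step_sd must divide range_sd")
    s = np.arange(-round(n), round(n) + 1) * step_sd
    points = axis.origin + np.outer(s * axis.sd, axis.direction)
    return s, points


def back_project(point: np.ndarray, scaler: ZScaler, embedding: EmbeddingModel,
                 image_shape: tuple[int, int], *,
                 invert_tol: float = 0.05, max_iter: int = 200,
                 presmooth_sigma: float = 1.5) -> np.ndarray:
    """Back-project an embedding-space point to an image.

    Reverses the z-scoring, inverts the PCA to the 5-channel space, splits the
    sample into the (dx, dy) warp field and the shape-free texture, inverts
    the field, and unwarps the texture back to image geometry. Points far
    along the axis can reconstruct slightly non-smooth fields; when the
    fold-over precondition or the inversion fails, the field is Gaussian
    pre-smoothed once before giving up.
    """
    emb = scaler.inverse_transform(np.asarray(point, dtype=np.float64))
    sample = inverse_transform(embedding, emb)
    arr = registration.unflatten_sample(sample, image_shape)
    warp = arr[..., :2].copy()
    texture = np.clip(arr[..., 2:5], 0.0, 1.0)

    def _smooth(w, sigma):
        return np.stack([ndimage.gaussian_filter(w[..., i], sigma,
                                                 mode="nearest")
                         for i in range(2)], axis=-1)

    # Far extrapolations can reconstruct locally non-smooth fields. The
    # smoothness precondition (displacement gradient < 1) is checked and, if
    # violated, the field is Gaussian pre-smoothed with escalating strength;
    # the damped fixed-point inversion is still attempted for borderline
    # fields, and only a genuinely non-invertible field raises.
    grad = registration.warp_gradient_magnitude(warp)
    if grad >= 1.0:
        warp = _smooth(warp, presmooth_sigma)
        grad = registration.warp_gradient_magnitude(warp)
    inv = None
    for attempt, sigma in enumerate(
            (None, presmooth_sigma, 2 * presmooth_sigma, 4 * presmooth_sigma)):
        if sigma is not None:
            warp = _smooth(warp, sigma)
        try:
            inv = registration.invert_warp(warp, tol=invert_tol,
                                           max_iter=max_iter)
            break
        except registration.WarpInversionError:
            continue
    if inv is None:
        raise FoldOverError(registration.warp_gradient_magnitude(warp))
    image = registration.apply_warp(texture, inv)
    return np.clip(image, 0.0, 1.0)


def unsharp_mask(image: np.ndarray, radius: float = 2.0,
                 amount: float = 0.8) -> np.ndarray:
    """Contrast enhancement for visualisation:
    image + amount * (image - low-pass(image)), clipped to [0, 1]."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    img = np.asarray(image, dtype=np.float64)
    if amount == 0:
        return img.copy()
    if img.ndim == 3:
        low = np.stack([ndimage.gaussian_filter(img[..., c], radius,
                                                mode="nearest")
                        for c in range(img.shape[-1])], axis=-1)
    else:
        low = ndimage.gaussian_filter(img, radius, mode="nearest")
    return np.clip(img + amount * (img - low), 0.0, 1.0)


def axis_feature_profile(positions, features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature curves along the discriminant axis.

    ``features`` holds one row per grid position (e.g. 13 rows for the default
    grid) with one column per facial feature. Returns, per feature, the
    Spearman monotone-trend statistic of feature value against axis position;
    features with no variation (e.g. action units never detected in any
    image) are flagged detected=False with trend 0.
    """
    positions = np.asarray(positions, dtype=float)
    if len(features) != positions.size:
        raise ValueError(
            f"feature table has {len(features)} rows but there are "
            f"{positions.size} grid positions")
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        if np.ptp(vals) <= 1e-12:
            rows.append({"feature": col, "trend": 0.0, "p": np.nan,
                         "detected": False})
            continue
        rho, p = stats.spearmanr(positions, vals)
        rows.append({"feature": col, "trend": float(rho), "p": float(p),
                     "detected": True})
    return pd.DataFrame(rows)
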