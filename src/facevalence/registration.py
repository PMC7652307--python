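"""Dense two-frame registration of face frames to a reference.

Each frame is registered to a reference image by a gradient-based (spatial
derivative constraint) estimator run coarse-to-fine over a Gaussian pyramid
with iterative refinement, in the spirit of multi-channel gradient motion
models used for face registration. The estimated warp field uses the backward
convention: the value stored at reference pixel p is the displacement d(p)
such that sampling the source at p + d(p) reproduces the reference. Backward
mapping makes warp application a single interpolation and makes inversion a
well-posed fixed-point problem.

The reference itself is estimated iteratively: starting from a single frame,
all frames are registered to the current reference and the reference is
replaced by the mean warped texture; by default this is repeated three times
to let the reference stabilise. Each registered frame is finally represented
as a 5-channel image (dx, dy, warped R, G, B) on the reference grid — the
"shape-free" texture plus the shape change needed to produce it.

Coordinates are 0-based pixel centres; displacements are in pixels of the
working grid. Out-of-bounds samples clamp to the nearest edge value (faces
are centred, borders are uniform background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .core import Clip


class WarpInversionError(RuntimeError):
    """Fixed-point inversion failed to converge; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"warp inversion did not reach tolerance after {max_iter} "
            f"iterations (residual {residual:.4f} px)")
        self.residual = residual


@dataclass
class WarpConfig:
    """Engine configuration for the gradient-based estimator.

    ``n_levels`` caps the pyramid depth (None = as deep as the image allows
    with a minimum level size of ``min_level_size``). ``window_sigma`` is the
    Gaussian aggregation window of the local normal equations; larger windows
    trade locality for robustness. ``field_sigma`` smooths the incremental
    field, regularising the estimate toward smooth deformations.
    Defaults were chosen to recover sub-pixel translations and smooth
    synthetic deformations on rendered faces.
    """

    n_levels: int | None = None
    min_level_size: int = 16
    iters_per_level: int = 6
    window_sigma: float = 3.0
    field_sigma: float = 0.8
    reg: float = 1e-4
    max_step: float = 2.0   # per-iteration displacement cap, px
    step_tol: float = 0.01  # mean |step| below which a level terminates early
    diffuse_sigma: float = 8.0  # confidence diffusion length, px
    conf_floor: float = 1e-3    # gradient-energy level treated as confident


DEFAULT_CONFIG = WarpConfig()


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    return img.mean(axis=-1) if img.ndim == 3 else img


def _pyramid(image: np.ndarray, cfg: WarpConfig) -> list[np.ndarray]:
    levels = [image]
    while min(levels[-1].shape) >= 2 * cfg.min_level_size and \
            (cfg.n_levels is None or len(levels) < cfg.n_levels):
        smoothed = ndimage.gaussian_filter(levels[-1], 1.0, mode="nearest")
        levels.append(smoothed[::2, ::2])
    return levels[::-1]  # coarse to fine


_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _grid(shape: tuple[int, int]) -> np.ndarray:
    if shape not in _GRID_CACHE:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        _GRID_CACHE[shape] = np.stack([yy, xx])
    return _GRID_CACHE[shape]


def _sample(image: np.ndarray, warp: np.ndarray) -> np.ndarray:
    base = _grid(image.shape[:2])
    coords = np.stack([base[0] + warp[..., 1], base[1] + warp[..., 0]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def estimate_warp(source: np.ndarray, reference: np.ndarray,
                  cfg: WarpConfig | None = None,
                  init: np.ndarray | None = None) -> np.ndarray:
    """Estimate the backward warp field registering ``source`` to
    ``reference``.

    Returns an (H, W, 2) array with channels (dx, dy): sampling the source at
    (x + dx, y + dy) approximates the reference at (x, y). The estimator
    guarantees in practice (and tests assert) that warping the source reduces
    its residual against the reference.

    ``init`` optionally warm-starts the coarsest pyramid level from a
    previous full-resolution field (e.g. the preceding frame of the same
    clip); the coarse-to-fine refinement then only needs to track the frame-
    to-frame change, which cuts iterations substantially on video input.
    """
    cfg = cfg or DEFAULT_CONFIG
    src = _to_gray(source)
    ref = _to_gray(reference)
    if src.shape != ref.shape:
        raise ValueError(f"shape mismatch: source {src.shape} vs reference {ref.shape}")
    if not (np.isfinite(src).all() and np.isfinite(ref).all()):
        raise ValueError("non-finite pixel values")

    src_pyr = _pyramid(src, cfg)
    ref_pyr = _pyramid(ref, cfg)

    d = np.zeros(src_pyr[0].shape + (2,))
    if init is not None and init.shape[:2] == src.shape:
        factor = src_pyr[0].shape[0] / src.shape[0]
        d = factor * resize(init, src_pyr[0].shape + (2,), order=1,
                            mode="edge", anti_aliasing=False)
    for s_l, r_l in zip(src_pyr, ref_pyr):
        if d.shape[:2] != s_l.shape:
            d = 2.0 * resize(d, s_l.shape + (2,), order=1, mode="edge",
                             anti_aliasing=False)
        gy_r, gx_r = np.gradient(r_l)
        for _ in range(cfg.iters_per_level):
            warped = _sample(s_l, d)
            gy_w, gx_w = np.gradient(warped)
            gx = 0.5 * (gx_w + gx_r)
            gy = 0.5 * (gy_w + gy_r)
            it = warped - r_l

            prods = np.stack([gx * gx, gy * gy, gx * gy, gx * it, gy * it])
            prods = ndimage.gaussian_filter(
                prods, (0, cfg.window_sigma, cfg.window_sigma),
                mode="nearest", truncate=3.0)
            a11 = prods[0] + cfg.reg
            a22 = prods[1] + cfg.reg
            a12 = prods[2]
            b1, b2 = -prods[3], -prods[4]
            det = a11 * a22 - a12 * a12
            step = np.stack([(a22 * b1 - a12 * b2) / det,
                             (a11 * b2 - a12 * b1) / det], axis=-1)
            np.clip(step, -cfg.max_step, cfg.max_step, out=step)
            if cfg.field_sigma > 0:
                step = ndimage.gaussian_filter(
                    step, (cfg.field_sigma, cfg.field_sigma, 0),
                    mode="nearest", truncate=3.0)
            d = d + step
            if np.mean(np.abs(step)) < cfg.step_tol:
                break
    # The data term says nothing about uniform regions (background, flat
    # shading): replace low-confidence estimates by a normalized-convolution
    # diffusion of confident ones, so warm-started fields cannot carry stale
    # displacements where nothing constrains them.
    if cfg.diffuse_sigma > 0:
        gy_r, gx_r = np.gradient(ref)
        conf = ndimage.gaussian_filter(gx_r ** 2 + gy_r ** 2,
                                       cfg.window_sigma, mode="nearest")
        num = ndimage.gaussian_filter(conf[..., None] * d,
                                      (cfg.diffuse_sigma, cfg.diffuse_sigma, 0),
                                      mode="nearest")
        den = ndimage.gaussian_filter(conf, cfg.diffuse_sigma,
                                      mode="nearest") + 1e-300
        d_diffused = num / den[..., None]
        alpha = (conf / (conf + cfg.conf_floor))[..., None]
        d = alpha * d + (1.0 - alpha) * d_diffused
    # Monotone contract: warping must not increase the residual; fall back to
    # the identity field in the (degenerate) case where it would.
    if np.sqrt(np.mean((_sample(src, d) - ref) ** 2)) > \
            np.sqrt(np.mean((src - ref) ** 2)):
        d = np.zeros_like(d)
    return d


def apply_warp(image: np.ndarray, warp: np.ndarray) -> np.ndarray:
    """Backward-sample ``image`` through ``warp`` with bilinear interpolation.

    Out-of-bounds samples take the nearest edge value. Multi-channel images
    are warped channel-wise.
    """
    image = np.asarray(image, dtype=float)
    if warp.shape[:2] != image.shape[:2]:
        raise ValueError(f"shape mismatch: image {image.shape[:2]} vs warp "
                         f"{warp.shape[:2]}")
    if image.ndim == 2:
        return _sample(image, warp)
    return np.stack([_sample(image[..., c], warp)
                     for c in range(image.shape[-1])], axis=-1)


def invert_warp(warp: np.ndarray, tol: float = 0.05,
                max_iter: int = 100) -> np.ndarray:
    """Invert a backward warp field by fixed-point iteration.

    Solves d_inv(p) = -d(p + d_inv(p)); requires the field to be fold-over
    free (displacement gradient magnitude < 1). On success, composing the
    warp with its inverse moves no point by more than ``tol`` px (interior,
    away from the clamped border).
    """
    d_inv = -warp.copy()
    border = 3
    interior = (slice(border, -border), slice(border, -border))
    residual = np.inf
    for _ in range(max_iter):
        dx = _sample(warp[..., 0], d_inv)
        dy = _sample(warp[..., 1], d_inv)
        new = -np.stack([dx, dy], axis=-1)
        d_inv = 0.5 * (d_inv + new)  # damped update for stability
        comp_x = d_inv[..., 0] + _sample(warp[..., 0], d_inv)
        comp_y = d_inv[..., 1] + _sample(warp[..., 1], d_inv)
        residual = float(np.max(np.hypot(comp_x[interior], comp_y[interior])))
        if residual <= tol:
            return d_inv
    raise WarpInversionError(residual, max_iter)


def warp_gradient_magnitude(warp: np.ndarray) -> float:
    """Largest displacement-gradient magnitude; >= 1 indicates fold-over."""
    gyx, gxx = np.gradient(warp[..., 0])
    gyy, gxy = np.gradient(warp[..., 1])
    return float(np.max(np.abs([gxx, gyx, gxy, gyy])))


# ---------------------------------------------------------------------------
# Crop / downsample
# ---------------------------------------------------------------------------

def crop_and_downsample(clip: Clip, bbox: tuple[int, int, int],
                        out_size: int = 128) -> Clip:
    """Crop every frame to a square bbox (x0, y0, side) and resample to
    out_size x out_size with anti-aliasing (low-pass prefilter)."""
    x0, y0, side = bbox
    h, w = clip.image_size
    if side <= 0:
        raise ValueError("bbox side must be positive (bbox must be square)")
    if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
        raise ValueError(f"bbox {bbox} outside frame of size {(h, w)}")
    out = []
    for frame in clip.frames:
        sub = frame[y0:y0 + side, x0:x0 + side]
        if side == out_size:
            out.append(sub.copy())
        else:
            out.append(resize(sub, (out_size, out_size, 3),
                              anti_aliasing=side > out_size, mode="edge"))
    import dataclasses
    return Clip(frames=np.stack(out),
                meta=dataclasses.replace(clip.meta), latents=clip.latents)


# ---------------------------------------------------------------------------
# Reference estimation and dataset registration
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTemplate:
    """Mean warped texture serving as registration target.

    ``change_norms`` records the mean absolute reference change per update
    iteration (a stability diagnostic; it should be non-increasing).
    """

    image: np.ndarray
    change_norms: list[float] = field(default_factory=list)
    init_frame: int = 0
    n_iterations: int = 3


def build_reference(frames: np.ndarray, init_frame: int | None = None,
                    n_iterations: int = 3,
                    cfg: WarpConfig | None = None) -> ReferenceTemplate:
    """Iteratively estimate the average-texture reference.

    Starting from a single frame (default: the temporally middle one), each
    iteration registers all frames to the current reference and replaces the
    reference with the mean warped texture.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (N, H, W, 3) array")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if init_frame is None:
        init_frame = frames.shape[0] // 2
    reference = frames[init_frame].copy()
    change_norms = []
    for _ in range(n_iterations):
        acc = np.zeros_like(reference)
        prev = None
        for f in frames:
            w = estimate_warp(f, reference, cfg, init=prev)
            prev = w
            acc += apply_warp(f, w)
        new_ref = acc / frames.shape[0]
        change_norms.append(float(np.mean(np.abs(new_ref - reference))))
        reference = new_ref
    return ReferenceTemplate(image=reference, change_norms=change_norms,
                             init_frame=init_frame, n_iterations=n_iterations)


def register_frame(frame: np.ndarray, reference: np.ndarray,
                   cfg: WarpConfig | None = None,
                   init: np.ndarray | None = None) -> np.ndarray:
    """Register one frame: returns the (H, W, 5) representation
    (dx, dy, warped R, warped G, warped B) on the reference grid."""
    w = estimate_warp(frame, reference, cfg, init=init)
    tex = np.clip(apply_warp(frame, w), 0.0, 1.0)
    return np.concatenate([w, tex], axis=-1)


def register_dataset(clips: list[Clip], reference: ReferenceTemplate | np.ndarray,
                     cfg: WarpConfig | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Register every frame of every clip to the reference.

    Returns a float32 stack of shape (n_samples, H, W, 5) and an index
    DataFrame mapping each sample row to (clip_id, frame). Flattened samples
    have length H * W * 5 (81,920 for 128-px frames).
    """
    ref = reference.image if isinstance(reference, ReferenceTemplate) else reference
    samples = []
    rows = []
    for clip in clips:
        prev = None  # warm-start within a clip; reset at clip boundaries
        for t in range(clip.n_frames):
            try:
                rf = register_frame(clip.frames[t], ref, cfg, init=prev)
                prev = rf[..., :2].astype(np.float64)
                samples.append(rf.astype(np.float32))
            except Exception as exc:
                raise RuntimeError(
                    f"registration failed for clip {clip.meta.clip_id} "
                    f"frame {t}: {exc}") from exc
            rows.append({"clip_id": clip.meta.clip_id, "frame": t})
    return np.stack(samples), pd.DataFrame(rows)


def register_subject(clips: list[Clip], n_iterations: int = 3,
                     cfg: WarpConfig | None = None,
                     init: tuple[int, int] | None = None
                     ) -> tuple[ReferenceTemplate, np.ndarray, pd.DataFrame]:
    """Full per-subject pipeline: build the reference from all frames of all
    clips, then register every frame to it.

    ``init`` selects the initial reference frame as (clip_index, frame_index);
    the default is the temporally middle frame of the first clip.
    """
    if not clips:
        raise ValueError("no clips supplied")
    all_frames = np.concatenate([c.frames for c in clips], axis=0)
    if init is None:
        init_global = clips[0].n_frames // 2
    else:
        ci, fi = init
        init_global = sum(c.n_frames for c in clips[:ci]) + fi
    reference = build_reference(all_frames, init_frame=init_global,
                                n_iterations=n_iterations, cfg=cfg)
    stack, index = register_dataset(clips, reference, cfg)
    return reference, stack, index


def flatten_stack(stack: np.ndarray) -> np.ndarray:
    """Flatten (n, H, W, 5) registered samples to (n, H*W*5) feature vectors."""
    return stack.reshape(stack.shape[0], -1)


def unflatten_sample(vec: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Reshape a flat sample back to (H, W, 5)."""
    h, w = shape
    return np.asarray(vec).reshape(h, w, 5)
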