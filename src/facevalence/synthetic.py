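"""Synthetic face-video generator with a controllable valence signal.

Real recordings of people delivering good and bad news are not publicly
available, so this module synthesises schematic face clips in which the two
valence classes differ systematically in a small set of latent expression
parameters — foremost a raising/dipping of the head, plus lip-corner curvature
and inner-brow elevation. Each phrase carries an idiosyncratic offset drawn
once per (class, phrase), and each repeat adds frame-level noise, so that
leave-one-phrase-out generalisation is a genuine test of ignoring phrase
idiosyncrasies rather than memorising them.

The renderer is deliberately schematic (smoothly shaded geometric primitives),
not photorealistic: dense gradient-based registration only requires smooth,
textured, deformable images, and schematic rendering keeps every fixture fast
and bit-deterministic. All face geometry is drawn in a head-local coordinate
frame, so a pure change in head position translates the whole image exactly.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CLIP_TYPES, VALENCE_CLASSES, Clip, ClipMetadata

# Field order of the latent expression vector.
PARAM_FIELDS = (
    "head_dy", "head_pitch", "head_yaw", "head_roll",
    "mouth_curve", "brow_raise", "texture_jitter",
)

# Natural per-field scales used to convert the dimensionless phrase/repeat
# noise magnitudes into each parameter's own units (px, deg, a.u.).
PARAM_NATURAL_SCALE = np.array([2.0, 2.0, 2.0, 1.0, 0.3, 0.15, 0.0])

_PARAM_BOUNDS = {
    "head_dy": (-12.0, 12.0),
    "head_pitch": (-20.0, 20.0),
    "head_yaw": (-20.0, 20.0),
    "head_roll": (-20.0, 20.0),
    "mouth_curve": (-1.5, 1.5),
    "brow_raise": (-1.5, 1.5),
    "texture_jitter": (0.0, 0.2),
}


@dataclass(frozen=True)
class ExpressionParams:
    """Latent parameters of a rendered face.

    head_dy is the vertical head offset in pixels of a 128-px face
    (positive = raised); pitch/yaw/roll are head-orientation proxies in
    degrees; mouth_curve is dimensionless lip-corner curvature (positive =
    upturned); brow_raise is dimensionless inner-brow elevation;
    texture_jitter scales a fixed procedural skin texture in [0, 0.2].
    """

    head_dy: float = 0.0
    head_pitch: float = 0.0
    head_yaw: float = 0.0
    head_roll: float = 0.0
    mouth_curve: float = 0.0
    brow_raise: float = 0.0
    texture_jitter: float = 0.0

    def validate(self) -> None:
        for name, (lo, hi) in _PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not np.isfinite(v) or not (lo <= v <= hi):
                raise ValueError(
                    f"ExpressionParams.{name}={v} outside valid range [{lo}, {hi}]")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ExpressionParams":
        return cls(**dict(zip(PARAM_FIELDS, np.asarray(v, dtype=float))))

    def clipped(self) -> "ExpressionParams":
        """Return a copy with every field clipped into its valid range."""
        vals = {}
        for name, (lo, hi) in _PARAM_BOUNDS.items():
            vals[name] = float(np.clip(getattr(self, name), lo, hi))
        return ExpressionParams(**vals)


# Class mean difference injected between positive and negative deliveries:
# positive valence raises the head, turns the lip corners up and lifts the
# inner brows; negative valence mirrors these.
DEFAULT_VALENCE_EFFECT = ExpressionParams(
    head_dy=3.0, head_pitch=4.0, mouth_curve=0.5, brow_raise=0.25)

# Resting face around which all latent trajectories vary.
DEFAULT_BASELINE = ExpressionParams(texture_jitter=0.05)


@dataclass
class DatasetSpec:
    """Design of a synthetic recording session.

    Defaults mirror the reference recording design: 3 subjects, 10 phrases per
    valence class, 15/15/16 repeats, 36-frame prefix clips and variable-length
    suffix clips. ``valence_effect`` is the class mean difference of the
    latent parameters (positive class gets +effect/2 at full ramp, negative
    class −effect/2, so the class difference equals the stated effect);
    ``phrase_sd`` and ``repeat_sd`` are dimensionless multipliers of each
    parameter's natural scale.
    """

    n_subjects: int = 3
    phrases_per_class: int = 10
    repeats_per_subject: tuple[int, ...] = (15, 15, 16)
    n_frames_prefix: int = 36
    suffix_frame_range: tuple[int, int] = (20, 48)
    image_size: int = 128
    valence_effect: ExpressionParams = field(
        default_factory=lambda: DEFAULT_VALENCE_EFFECT)
    baseline: ExpressionParams = field(default_factory=lambda: DEFAULT_BASELINE)
    phrase_sd: float = 0.5
    repeat_sd: float = 0.25
    ramp_floor: float = 0.3
    clip_types: tuple[str, ...] = CLIP_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phrases_per_class < 2:
            raise ValueError("phrases_per_class must be >= 2")
        if len(self.repeats_per_subject) != self.n_subjects:
            raise ValueError("repeats_per_subject must have one entry per subject")
        if any(r < 2 for r in self.repeats_per_subject):
            raise ValueError("every subject needs >= 2 repeats")
        if self.n_frames_prefix < 2:
            raise ValueError("n_frames_prefix must be >= 2")
        lo, hi = self.suffix_frame_range
        if lo < 2 or hi < lo:
            raise ValueError("suffix_frame_range must satisfy 2 <= min <= max")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        unknown = set(self.clip_types) - set(CLIP_TYPES)
        if unknown:
            raise ValueError(f"unknown clip types: {sorted(unknown)}")

    @property
    def subject_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_subjects)]

    def replace(self, **kw) -> "DatasetSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "DatasetSpec":
        """Load a spec from a YAML file whose keys map 1:1 to the fields;
        ExpressionParams fields are nested mappings."""
        import yaml
        raw = yaml.safe_load(open(path)) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown DatasetSpec keys: {sorted(unknown)}")
        for key in ("valence_effect", "baseline"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = ExpressionParams(**raw[key])
        for key in ("repeats_per_subject", "suffix_frame_range", "clip_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        d = dataclasses.asdict(self)
        d["repeats_per_subject"] = list(self.repeats_per_subject)
        d["suffix_frame_range"] = list(self.suffix_frame_range)
        d["clip_types"] = list(self.clip_types)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray, edge: float) -> np.ndarray:
    """Soft 0/1 transition of width ~edge around x = 0 (positive inside)."""
    return 0.5 * (1.0 + np.tanh(x / edge))


def render_face_frame(params: ExpressionParams, size: int = 128) -> np.ndarray:
    """Render a schematic face as an RGB image in [0, 1].

    Rendering is a deterministic, smooth function of the parameters. All
    facial geometry is expressed in head-local coordinates obtained by
    translating the grid by the head offset and rotating by head roll, so a
    change in head_dy alone translates the image exactly. The output is
    quantised to the 8-bit grid so lossless PNG round trips are bit-identical.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    params.validate()

    s = size / 128.0  # geometry scale relative to the reference 128-px face
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = (size - 1) / 2.0
    cy = (size - 1) / 2.0 - params.head_dy * s  # + head_dy = raised = up

    th = np.deg2rad(params.head_roll)
    u = np.cos(th) * (xx - cx) + np.sin(th) * (yy - cy)
    v = -np.sin(th) * (xx - cx) + np.cos(th) * (yy - cy)

    # Head outline: soft ellipse with radial shading.
    ax_, bx_ = 44.0 * s, 56.0 * s
    r2 = (u / ax_) ** 2 + (v / bx_) ** 2
    head = _smoothstep(1.0 - r2, 0.08)
    shade = 1.0 - 0.25 * np.clip(r2, 0.0, 1.0)

    # Internal features shift with pitch (chin-raise proxy: features move up)
    # and yaw (left/right turn: features shift sideways).
    dv = -params.head_pitch * 0.8 * s
    du = params.head_yaw * 0.8 * s
    uf, vf = u - du, v - dv

    dark = np.zeros_like(u)

    # Eyes.
    for sx in (-1.0, 1.0):
        e2 = ((uf - sx * 17.0 * s) / (6.5 * s)) ** 2 + ((vf + 10.0 * s) / (4.0 * s)) ** 2
        dark += 0.85 * np.exp(-e2 * 1.2)

    # Brows: soft horizontal bars above the eyes, raised by brow_raise.
    brow_v = -21.0 * s - params.brow_raise * 6.0 * s
    for sx in (-1.0, 1.0):
        b_lat = np.exp(-(((uf - sx * 17.0 * s) / (8.0 * s)) ** 2))
        b_vert = np.exp(-(((vf - brow_v) / (2.2 * s)) ** 2))
        dark += 0.55 * b_lat * b_vert

    # Nose: faint vertical ridge for mid-face texture.
    dark += 0.25 * np.exp(-((uf / (3.0 * s)) ** 2 + ((vf - 2.0 * s) / (10.0 * s)) ** 2))

    # Mouth: dark band along a parabola; positive curvature lifts the corners.
    half_w = 16.0 * s
    t = uf / half_w
    mouth_v = 26.0 * s - params.mouth_curve * 7.0 * s * t ** 2
    m_lat = np.exp(-np.clip(t ** 2, 0, 50.0) ** 2 * 0.5)
    m_vert = np.exp(-(((vf - mouth_v) / (2.6 * s)) ** 2))
    dark += 0.8 * m_lat * m_vert

    # Fixed procedural skin texture in head-local coordinates.
    if params.texture_jitter > 0:
        k = 1.0 / s
        tex = (np.sin(0.23 * k * u + 0.11 * k * v)
               + np.sin(0.09 * k * u - 0.31 * k * v + 1.3)
               + np.sin(0.41 * k * u + 0.07 * k * v + 2.1)) / 3.0
        dark -= params.texture_jitter * tex

    skin = np.array([0.85, 0.68, 0.55])
    background = 0.35
    dark = np.clip(dark, 0.0, 1.2)
    img = np.empty((size, size, 3))
    for c in range(3):
        face_c = skin[c] * shade * (1.0 - 0.75 * np.clip(dark, 0, 1))
        img[..., c] = background + head * (face_c - background)

    img = np.clip(img, 0.0, 1.0)
    return np.round(img * 255.0) / 255.0


def mouth_region_mask(size: int = 128, margin: int = 4) -> np.ndarray:
    """Boolean mask covering every pixel the mouth band can occupy for
    |mouth_curve| <= 1 at neutral head pose, padded by ``margin`` px.

    Derived from the renderer's own mouth geometry; used as an oracle for
    locality tests of mouth_curve.
    """
    s = size / 128.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2.0
    u, v = xx - c, yy - c
    half_w = 16.0 * s
    t = u / half_w
    lo = 26.0 * s - 7.0 * s * t ** 2   # curve = +1
    hi = 26.0 * s + 7.0 * s * t ** 2   # curve = -1
    band = (v >= np.minimum(lo, hi) - (2.6 * 3) * s - margin) & \
           (v <= np.maximum(lo, hi) + (2.6 * 3) * s + margin)
    lateral = np.abs(t) <= 2.0
    return band & lateral


# ---------------------------------------------------------------------------
# Probes (renderer-aware measurements used for sign/effect recovery checks)
# ---------------------------------------------------------------------------

def measure_vertical_shift(image: np.ndarray, relative_to: np.ndarray) -> float:
    """Estimate the global vertical displacement of ``image`` relative to
    ``relative_to`` by phase cross-correlation. Positive = image content
    sits higher (head raised)."""
    from skimage.registration import phase_cross_correlation

    a = image.mean(axis=-1) if image.ndim == 3 else image
    b = relative_to.mean(axis=-1) if relative_to.ndim == 3 else relative_to
    shift, _, _ = phase_cross_correlation(b, a, upsample_factor=20)
    # shift[0] is the row shift that moves `a` onto `b`: a face raised by
    # k px needs shifting down (+k rows) to match, so shift[0] is already
    # positive-up.
    return float(shift[0])


def measure_face_elevation(image: np.ndarray) -> float:
    """Vertical position of the face relative to the image centre, in px
    (positive = raised), estimated from the intensity-weighted centroid of
    the non-background region. Robust to deformations because it uses the
    whole face mass rather than feature matching."""
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    border = np.concatenate([gray[0], gray[-1], gray[:, 0], gray[:, -1]])
    bg = float(np.median(border))
    w = np.abs(gray - bg)
    total = w.sum()
    if total <= 1e-9:
        return 0.0
    rows = np.arange(gray.shape[0], dtype=float)
    centroid = float((w.sum(axis=1) * rows).sum() / total)
    return (gray.shape[0] - 1) / 2.0 - centroid


def measure_mouth_curvature(image: np.ndarray, size: int | None = None) -> float:
    """Estimate mouth_curve from an image by tracing the dark mouth band.

    Within the renderer's mouth region, the darkest row is located per column
    (the mouth line is the darkest structure there) with sub-pixel parabolic
    refinement, and a quadratic is fitted across columns; the negated,
    rescaled quadratic coefficient recovers the curvature parameter. Head
    offsets of a few pixels only bias the constant term, not the curvature.
    """
    if size is None:
        size = image.shape[0]
    s = size / 128.0
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    # The mask assumes a centred face; follow the face if the head is
    # raised/dipped so the window still contains the mouth.
    dy = measure_face_elevation(image)
    mask = np.roll(mouth_region_mask(size, margin=4), -int(round(dy)), axis=0)
    c = (size - 1) / 2.0
    t_cols = (np.arange(size) - c) / (16.0 * s)
    ts, vs = [], []
    for j in np.flatnonzero(np.abs(t_cols) <= 1.0):
        rows = np.flatnonzero(mask[:, j])
        if rows.size < 3:
            continue
        col = gray[rows, j]
        i = int(np.argmin(col))
        v = float(rows[i])
        if 0 < i < col.size - 1:  # parabolic sub-pixel refinement
            denom = col[i - 1] - 2 * col[i] + col[i + 1]
            if denom > 1e-12:
                v += 0.5 * (col[i - 1] - col[i + 1]) / denom
        ts.append(t_cols[j])
        vs.append(v)
    if len(ts) < 5:
        return 0.0
    ts, vs = np.asarray(ts), np.asarray(vs)
    # Median-band estimator: compare the band centre against the corners.
    # Medians make the probe robust to occasional columns where a darker
    # structure (chin shading, face boundary) wins the argmin.
    centre = np.abs(ts) <= 0.3
    corner = (np.abs(ts) >= 0.6) & (np.abs(ts) <= 0.95)
    if centre.sum() < 2 or corner.sum() < 2:
        return 0.0
    v_centre = float(np.median(vs[centre]))
    v_corner = float(np.median(vs[corner]))
    t2 = float(np.median(ts[corner] ** 2))
    return (v_centre - v_corner) / (7.0 * s * t2)


# ---------------------------------------------------------------------------
# Clip simulation
# ---------------------------------------------------------------------------

def raised_cosine_ramp(n_frames: int, floor: float = 0.3) -> np.ndarray:
    """Smooth ramp over the clip (raised cosine from ``floor`` to 1), so the
    expression deepens over time as in a natural delivery.

    The floor is non-zero because a speaker already knows the valence of the
    message at phrase onset: natural deliveries carry expression information
    from the first frame, merely strengthening over the clip.
    """
    t = np.arange(n_frames, dtype=float)
    base = 0.5 * (1.0 - np.cos(np.pi * t / (n_frames - 1)))
    return floor + (1.0 - floor) * base


def _phrase_offset(spec: DatasetSpec, valence_class: str, phrase_id: int) -> np.ndarray:
    """Idiosyncratic latent offset of one (class, phrase), drawn once from
    spec.seed and shared by all repeats and subjects of that phrase."""
    cls_idx = VALENCE_CLASSES.index(valence_class)
    ss = np.random.SeedSequence(spec.seed, spawn_key=(7001, cls_idx, phrase_id))
    rng = np.random.default_rng(ss)
    off = rng.standard_normal(len(PARAM_FIELDS)) * spec.phrase_sd * PARAM_NATURAL_SCALE
    return off


def _clip_seed_sequence(spec: DatasetSpec, meta: ClipMetadata, seed: int | None):
    base = spec.seed if seed is None else seed
    cls_idx = VALENCE_CLASSES.index(meta.valence_class)
    type_idx = CLIP_TYPES.index(meta.clip_type)
    subj_idx = zlib.crc32(meta.subject_id.encode()) % (2**31)
    return np.random.SeedSequence(
        base, spawn_key=(subj_idx, cls_idx, meta.phrase_id, meta.repeat_index, type_idx))


def clip_frame_count(spec: DatasetSpec, meta: ClipMetadata, seed: int | None = None) -> int:
    """Frame count of a clip: fixed for prefix clips, drawn uniformly from
    suffix_frame_range for suffix clips (reproducible from the clip seed)."""
    if meta.clip_type == "prefix":
        return spec.n_frames_prefix
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed if seed is None else seed,
                               spawn_key=_clip_seed_sequence(spec, meta, seed).spawn_key + (99,)))
    lo, hi = spec.suffix_frame_range
    return int(rng.integers(lo, hi + 1))


def simulate_latents(spec: DatasetSpec, meta: ClipMetadata,
                     seed: int | None = None) -> np.ndarray:
    """Per-frame latent parameter vectors for one clip.

    latent(t) = baseline + class_sign * effect/2 * ramp(t)
              + phrase_offset(class, phrase) + repeat noise(t),
    with repeat noise i.i.d. per frame at repeat_sd times the natural scales.
    The positive class takes class_sign = +1, so the class mean difference of
    any parameter at full ramp equals the specified effect.
    """
    n = clip_frame_count(spec, meta, seed)
    ramp = raised_cosine_ramp(n, spec.ramp_floor)
    sign = 1.0 if meta.valence_class == "positive" else -1.0
    effect = spec.valence_effect.as_vector()
    base = spec.baseline.as_vector()
    off = _phrase_offset(spec, meta.valence_class, meta.phrase_id)

    rng = np.random.default_rng(_clip_seed_sequence(spec, meta, seed))
    noise = rng.standard_normal((n, len(PARAM_FIELDS))) * spec.repeat_sd * PARAM_NATURAL_SCALE

    lat = base[None, :] + sign * 0.5 * effect[None, :] * ramp[:, None] + off[None, :] + noise
    # Keep every frame renderable.
    bounds = np.array([_PARAM_BOUNDS[f] for f in PARAM_FIELDS])
    return np.clip(lat, bounds[:, 0], bounds[:, 1])


def simulate_clip(spec: DatasetSpec, meta: ClipMetadata,
                  seed: int | None = None) -> Clip:
    """Render one clip; fully reproducible from (spec.seed or seed, meta)."""
    lat = simulate_latents(spec, meta, seed)
    frames = np.stack([
        render_face_frame(ExpressionParams.from_vector(lat[t]), spec.image_size)
        for t in range(lat.shape[0])
    ])
    meta = dataclasses.replace(meta, n_frames=lat.shape[0])
    return Clip(frames=frames, meta=meta, latents=lat)


def dataset_metadata(spec: DatasetSpec) -> list[ClipMetadata]:
    """Full factorial clip design: one clip per
    (subject, class, phrase, repeat, clip type)."""
    metas = []
    for si, subject in enumerate(spec.subject_ids):
        for repeat in range(1, spec.repeats_per_subject[si] + 1):
            for vclass in VALENCE_CLASSES:
                for phrase in range(1, spec.phrases_per_class + 1):
                    for ctype in spec.clip_types:
                        metas.append(ClipMetadata(
                            subject_id=subject, phrase_id=phrase,
                            valence_class=vclass, repeat_index=repeat,
                            clip_type=ctype))
    return metas


def generate_dataset(spec: DatasetSpec, out_dir=None,
                     render: bool = True) -> tuple[list[Clip], pd.DataFrame]:
    """Generate all clips of the design and their manifest.

    With ``render=False`` the clips carry only latent trajectories (frames of
    length 0 are not created; metadata and manifest are still exact), which is
    useful when only the design arithmetic or the latents are needed.
    If ``out_dir`` is given the clips and manifest are written there
    (see io_formats.write_dataset).
    """
    metas = dataset_metadata(spec)
    clips = []
    for meta in metas:
        if render:
            clips.append(simulate_clip(spec, meta))
        else:
            lat = simulate_latents(spec, meta)
            m = dataclasses.replace(meta, n_frames=lat.shape[0])
            clips.append(Clip(frames=np.zeros((lat.shape[0], 1, 1, 3)),
                              meta=m, latents=lat))
    manifest = manifest_from_clips(clips)
    if out_dir is not None:
        from .io_formats import write_dataset
        write_dataset(clips, out_dir)
    return clips, manifest


def manifest_from_clips(clips: list[Clip]) -> pd.DataFrame:
    rows = []
    for c in clips:
        m = c.meta
        rows.append({
            "clip_id": m.clip_id, "subject": m.subject_id, "phrase": m.phrase_id,
            "class": m.valence_class, "repeat": m.repeat_index,
            "clip_type": m.clip_type, "n_frames": c.n_frames,
            "path": m.clip_id,
        })
    df = pd.DataFrame(rows)
    if df["clip_id"].duplicated().any():
        raise ValueError("duplicate clip identities in design")
    return df


# ---------------------------------------------------------------------------
# Synthetic facial-feature tables (action units + head pose)
# ---------------------------------------------------------------------------

def generate_feature_table(spec: DatasetSpec, manifest: pd.DataFrame,
                           seed: int | None = None, effect_size: float = 1.0,
                           noise_sd: float = 1.0) -> pd.DataFrame:
    """Per-frame facial-feature table in the 23-column action-unit + head-pose
    dialect (17 AU intensities, 6 pose parameters).

    The valence signal is injected into the features known to track valence:
    vertical head position (pose_Ty, up with positive valence), head pitch
    (pose_Rx, raised with positive valence), inner-brow raiser (AU01), lip
    corner puller (AU12) and chin raiser (AU17), scaled by the same raised-
    cosine ramp as the video generator. All other columns carry pure noise.
    AU intensities are clipped at zero (they are non-negative by definition).
    """
    from .io_formats import AU_COLUMNS, POSE_COLUMNS

    base_seed = spec.seed if seed is None else seed
    affected_pose = {"pose_Ty": 1.0, "pose_Rx": 1.0}
    affected_aus = {"AU01_r": 0.8, "AU12_r": 1.0, "AU17_r": 0.6}

    frames_rows = []
    for _, row in manifest.iterrows():
        n = int(row["n_frames"])
        sign = 1.0 if row["class"] == "positive" else -1.0
        cls_idx = VALENCE_CLASSES.index(row["class"])
        ss = np.random.SeedSequence(
            base_seed, spawn_key=(5150, cls_idx, int(row["phrase"]), int(row["repeat"]),
                                  CLIP_TYPES.index(row["clip_type"]),
                                  zlib.crc32(str(row["subject"]).encode()) % (2**31)))
        rng = np.random.default_rng(ss)
        ramp = raised_cosine_ramp(n, spec.ramp_floor)
        # phrase idiosyncrasy in feature space, shared across repeats,
        # scaled by the design's phrase variability
        prng = np.random.default_rng(np.random.SeedSequence(
            base_seed, spawn_key=(5151, cls_idx, int(row.phrase))))
        phrase_off = prng.standard_normal(23) * spec.phrase_sd * noise_sd

        vals = rng.standard_normal((n, 23)) * noise_sd + phrase_off[None, :]
        cols = list(AU_COLUMNS) + list(POSE_COLUMNS)
        for col, w in {**affected_aus, **affected_pose}.items():
            j = cols.index(col)
            vals[:, j] += sign * 0.5 * effect_size * w * ramp
        # AU intensities: shift to a positive baseline and clip at zero.
        n_aus = len(AU_COLUMNS)
        vals[:, :n_aus] = np.clip(vals[:, :n_aus] + 1.5, 0.0, None)

        df = pd.DataFrame(vals, columns=cols)
        df.insert(0, "frame_index", np.arange(n))
        df.insert(0, "clip_id", row["clip_id"])
        frames_rows.append(df)
    return pd.concat(frames_rows, ignore_index=True)


def frame_index_from_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Expand a clip manifest into a per-frame sample index with columns
    (clip_id, subject, phrase, class, repeat, clip_type, frame)."""
    rows = []
    for _, row in manifest.iterrows():
        for t in range(int(row["n_frames"])):
            rows.append({
                "clip_id": row["clip_id"], "subject": row["subject"],
                "phrase": int(row["phrase"]), "class": row["class"],
                "repeat": int(row["repeat"]), "clip_type": row["clip_type"],
                "frame": t,
            })
    return pd.DataFrame(rows)


def generate_embedded_subjects(spec: DatasetSpec, effect_size: float = 2.0,
                               noise_sd: float = 1.0,
                               seed: int | None = None,
                               transform_subjects: bool = True):
    """Per-subject feature datasets sharing a common valence signal, each
    expressed in its own feature space.

    Every subject's samples carry the same class effect and the same phrase
    idiosyncrasies (plus independent subject noise); each subject's feature
    space is then rotated (random orthogonal matrix, reflections possible),
    globally rescaled and translated. Recovering the shared signal across
    subjects therefore requires an alignment step — the condition the
    cross-subject hyperalignment analysis is built for.

    Returns a list of hyperalign.SubjectData.
    """
    from .hyperalign import SubjectData
    from .io_formats import AU_COLUMNS, POSE_COLUMNS

    base_seed = spec.seed if seed is None else seed
    cols = list(AU_COLUMNS) + list(POSE_COLUMNS)
    _, manifest = generate_dataset(spec, render=False)
    rng = np.random.default_rng(np.random.SeedSequence(base_seed,
                                                       spawn_key=(9301,)))
    out = []
    for subject in spec.subject_ids:
        man_s = manifest[manifest["subject"] == subject].reset_index(drop=True)
        ft = generate_feature_table(spec, man_s, seed=base_seed,
                                    effect_size=effect_size, noise_sd=noise_sd)
        X = ft[cols].to_numpy()
        k = X.shape[1]
        if transform_subjects:
            R, _ = np.linalg.qr(rng.standard_normal((k, k)))
            scale = float(rng.uniform(0.5, 2.0))
            shift = rng.standard_normal(k) * 2.0
            X = scale * X @ R + shift
        out.append(SubjectData(subject=subject, samples=X,
                               index=frame_index_from_manifest(man_s)))
    return out


# ---------------------------------------------------------------------------
# Simulated human raters
# ---------------------------------------------------------------------------

def simulate_raters(axis_positions, n_raters: int, n_blocks: int = 4,
                    response_noise: float = 0.25, seed: int = 0,
                    gain: float = 1.0, subject: str = "s1",
                    clip_type: str = "prefix") -> pd.DataFrame:
    """Simulate raters judging valence of images sampled along the
    discriminant axis.

    Each rater's response to an image at ``position`` (in SD units) in each
    block is clip(gain * position / 3 + noise, -1, +1): a monotone mapping of
    axis position onto the rating scale plus independent Gaussian noise.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    positions = np.asarray(axis_positions, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(8101,)))
    records = []
    for r in range(n_raters):
        for b in range(1, n_blocks + 1):
            noise = rng.standard_normal(positions.size) * response_noise
            resp = np.clip(gain * positions / 3.0 + noise, -1.0, 1.0)
            for pos, x in zip(positions, resp):
                records.append({
                    "rater": f"r{r + 1}", "subject": subject,
                    "clip_type": clip_type, "position": pos,
                    "block": b, "response": x,
                })
    return pd.DataFrame(records)
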