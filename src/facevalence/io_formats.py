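"""Readers and writers for clip directories, manifests, feature tables and
results tables, with strict validation.

Clips are stored as directories of lossless PNG frames (``frame_%04d.png``)
plus a ``manifest.csv``; storing individual frames losslessly avoids any video
codec dependency while preserving bit-exact round trips. Feature tables use
the column-name dialect of the OpenFace 2.x facial-behaviour toolkit
(``AU01_r`` ... ``AU45_r``, ``pose_Tx`` ... ``pose_Rz``) so real exports can be
consumed unmodified. All CSV output is UTF-8, comma-separated, with a header
row, at 9 significant digits.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import Clip, ClipMetadata

AU_COLUMNS = (
    "AU01_r", "AU02_r", "AU04_r", "AU05_r", "AU06_r", "AU07_r", "AU09_r",
    "AU10_r", "AU12_r", "AU14_r", "AU15_r", "AU17_r", "AU20_r", "AU23_r",
    "AU25_r", "AU26_r", "AU45_r",
)
POSE_COLUMNS = ("pose_Tx", "pose_Ty", "pose_Tz", "pose_Rx", "pose_Ry", "pose_Rz")

MODEL_SUBSETS = {
    "aus": AU_COLUMNS,
    "pose": POSE_COLUMNS,
    "aus+pose": AU_COLUMNS + POSE_COLUMNS,
}

MANIFEST_COLUMNS = ("clip_id", "subject", "phrase", "class", "repeat",
                    "clip_type", "n_frames", "path")

_FLOAT_FORMAT = "%.9g"
_FRAME_RE = re.compile(r"^frame_(\d{4})\.png$")


class FormatError(ValueError):
    """A file failed validation against its expected on-disk format."""


# ---------------------------------------------------------------------------
# Clips
# ---------------------------------------------------------------------------

def write_clip(clip: Clip, path) -> Path:
    """Write a clip as a directory of 8-bit lossless PNG frames."""
    path = Path(path)
    if path.exists() and any(path.iterdir()):
        raise OSError(f"refusing to write clip into non-empty directory {path}")
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        arr = np.round(np.clip(frame, 0.0, 1.0) * 255.0).astype(np.uint8)
        iio.imwrite(path / f"frame_{i:04d}.png", arr)
    return path


def read_clip(path, metadata: ClipMetadata | None = None) -> Clip:
    """Read a clip directory; frames ordered by index, values in [0, 1].

    Raises FormatError when frame numbering has gaps, an image is unreadable,
    or the frame count disagrees with the supplied metadata.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"clip directory not found: {path}")
    indices = {}
    for p in path.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            indices[int(m.group(1))] = p
    if not indices:
        raise FormatError(f"no frame_NNNN.png files in {path}")
    order = sorted(indices)
    expected = range(order[0], order[0] + len(order))
    missing = sorted(set(expected) - set(order))
    if missing:
        raise FormatError(
            f"gap in frame numbering in {path}: missing frame_{missing[0]:04d}.png")
    frames = []
    for i in order:
        try:
            arr = iio.imread(indices[i])
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"unreadable frame image {indices[i]}: {exc}") from exc
        frames.append(arr.astype(float) / 255.0)
    frames = np.stack(frames)
    if metadata is not None and metadata.n_frames and metadata.n_frames != len(frames):
        raise FormatError(
            f"manifest says {metadata.n_frames} frames but {path} holds {len(frames)}")
    if metadata is None:
        metadata = ClipMetadata(subject_id="unknown", phrase_id=1,
                                valence_class="positive", repeat_index=1,
                                clip_type="prefix", n_frames=len(frames))
    return Clip(frames=frames, meta=metadata)


def write_dataset(clips: list[Clip], out_dir) -> Path:
    """Write clips plus manifest.csv into ``out_dir``."""
    from .synthetic import manifest_from_clips

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest_from_clips(clips)
    for clip in clips:
        write_clip(clip, out_dir / clip.meta.clip_id)
    write_manifest(manifest, out_dir / "manifest.csv")
    return out_dir


def write_manifest(manifest: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["clip_id"].duplicated().any():
        dup = df.loc[df["clip_id"].duplicated(), "clip_id"].iloc[0]
        raise FormatError(f"duplicate clip_id in manifest: {dup}")
    return df


def read_dataset(root) -> tuple[list[Clip], pd.DataFrame]:
    """Read manifest.csv and all clip directories under ``root``."""
    root = Path(root)
    manifest = read_manifest(root / "manifest.csv")
    clips = []
    for _, row in manifest.iterrows():
        meta = ClipMetadata(
            subject_id=str(row["subject"]), phrase_id=int(row["phrase"]),
            valence_class=str(row["class"]), repeat_index=int(row["repeat"]),
            clip_type=str(row["clip_type"]), n_frames=int(row["n_frames"]))
        clips.append(read_clip(root / str(row["path"]), meta))
    return clips, manifest


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_feature_table(path, model_subset: str = "aus+pose") -> pd.DataFrame:
    """Read a per-frame feature CSV and return the requested column subset.

    ``model_subset`` selects the 17 action-unit intensities ("aus"), the 6
    head-pose parameters ("pose"), or both ("aus+pose", 23 columns). Key
    columns (clip_id, frame_index) are preserved for joining to a manifest.
    """
    if model_subset not in MODEL_SUBSETS:
        raise ValueError(f"model_subset must be one of {sorted(MODEL_SUBSETS)}")
    df = pd.read_csv(path)
    want = MODEL_SUBSETS[model_subset]
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} missing columns: {missing}")
    keys = [c for c in ("clip_id", "frame_index") if c in df.columns]
    out = df.loc[:, keys + list(want)].copy()
    if out[list(want)].isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise FormatError(f"feature table {path} has missing cells in {bad}")
    au_present = [c for c in AU_COLUMNS if c in want]
    if au_present and (out[au_present].to_numpy() < 0).any():
        raise FormatError(f"negative action-unit intensity in {path}")
    return out


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

_CONFUSION_ROW_GROUPS = (
    ("p_pos_pos", "p_pos_neg"),
    ("p_neg_pos", "p_neg_neg"),
)


def validate_results(records: pd.DataFrame) -> None:
    if "accuracy" in records.columns:
        acc = records["accuracy"].to_numpy(dtype=float)
        if np.any(acc < -1e-9) or np.any(acc > 1 + 1e-9):
            raise FormatError("accuracy values must lie in [0, 1]")
    for group in _CONFUSION_ROW_GROUPS:
        if all(c in records.columns for c in group):
            sums = records[list(group)].to_numpy(dtype=float).sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise FormatError(
                    f"confusion proportions {group} must sum to 1 per row")


def write_results(records: pd.DataFrame, path) -> None:
    """Write a validated results CSV (fold accuracies, confusion proportions,
    test statistics)."""
    validate_results(records)
    records.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_results(df)
    return df


# ---------------------------------------------------------------------------
# Registered-stack container (binary array + JSON sidecar)
# ---------------------------------------------------------------------------

def save_registered_stack(stack: np.ndarray, index: pd.DataFrame, path) -> None:
    """Persist a registered 5-channel stack as .npy plus a JSON sidecar
    documenting shape, channel order and the sample index."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), stack.astype(np.float32))
    sidecar = {
        "shape": list(stack.shape),
        "channels": ["dx", "dy", "R", "G", "B"],
        "index": index.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_registered_stack(path) -> tuple[np.ndarray, pd.DataFrame]:
    path = Path(path)
    stack = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if list(stack.shape) != sidecar["shape"]:
        raise FormatError("registered stack shape disagrees with sidecar")
    return stack, pd.DataFrame(sidecar["index"])
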