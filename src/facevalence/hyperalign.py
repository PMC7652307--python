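"""Cross-subject alignment of embedding spaces and nested cross-validated
valence classification.

Different individuals' face spaces have no privileged dimension-to-dimension
correspondence, so subjects are aligned by Procrustes transforms (translation,
rotation/reflection, global scale) into a common group space, built in two
stages: a running group average is grown subject by subject, then every
subject's transform is refitted to the final average. Sample correspondence
across subjects is by (class, phrase, repeat, frame) index after the datasets
are equalised to common clip counts and clip lengths — the only ordering the
equalisation steps support.

Classification generality is evaluated by a nested scheme: an outer 5-fold
leave-two-phrases-out loop fits the (per-subject PCA and) Procrustes
parameters on 8 of the 10 phrases per class, and an inner 6-fold simultaneous
leave-one-subject-and-one-phrase-out loop fits the LDA inside the outer-test
phrases only — 30 folds in total with 3 subjects. Success therefore requires
generalisation across both subjects and phrases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from . import face_space
from .classify import CvResult, fit_lda, summarize_confusion, zscore_split


class CorrespondenceError(ValueError):
    """Subjects' sample indices do not align row-for-row."""


@dataclass
class ProcrustesTransform:
    """Similarity transform x -> scale * x @ rotation + translation
    (rotation orthogonal, reflections allowed)."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(X) @ self.rotation + self.translation

    def inverse(self) -> "ProcrustesTransform":
        Rinv = self.rotation.T
        return ProcrustesTransform(rotation=Rinv, scale=1.0 / self.scale,
                                   translation=-self.translation @ Rinv / self.scale)

    @classmethod
    def identity(cls, k: int) -> "ProcrustesTransform":
        return cls(rotation=np.eye(k), scale=1.0, translation=np.zeros(k))


def procrustes_fit(source_samples: np.ndarray,
                   target_samples: np.ndarray) -> ProcrustesTransform:
    """Least-squares similarity transform taking source rows onto target rows.

    Rows correspond one-to-one. The orthogonal factor may include reflections
    (no determinant correction), and the optimum can never be worse than the
    identity transform since the identity lies in the feasible set.
    """
    X = np.asarray(source_samples, dtype=np.float64)
    Y = np.asarray(target_samples, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    C = Xc.T @ Yc
    U, S, Vt = linalg.svd(C)
    if np.sum(S > 1e-12 * max(S[0], 1e-300)) < min(C.shape):
        warnings.warn("rank-deficient cross-covariance in Procrustes fit; "
                      "solution is a best-effort minimiser", RuntimeWarning)
    R = U @ Vt
    normX2 = float((Xc ** 2).sum())
    if normX2 <= 0:
        raise ValueError("source samples have zero variance")
    scale = float(S.sum() / normX2)
    t = my - scale * mx @ R
    return ProcrustesTransform(rotation=R, scale=scale, translation=t)


# ---------------------------------------------------------------------------
# Subject data and equalisation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One subject's sample matrix with its per-row index.

    ``index`` has columns clip_id, phrase, class, repeat, frame (and
    optionally clip_type); rows of ``samples`` correspond to rows of
    ``index``.
    """

    subject: str
    samples: np.ndarray
    index: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.index):
            raise ValueError("samples and index disagree in length")


_CORR_KEYS = ["class", "phrase", "repeat", "frame"]


def _corr_keys(index: pd.DataFrame) -> list[str]:
    keys = list(_CORR_KEYS)
    if "clip_type" in index.columns:
        keys.append("clip_type")
    return keys


def _assert_correspondence(datasets: list[SubjectData]) -> None:
    keys = _corr_keys(datasets[0].index)
    ref = datasets[0].index[keys].reset_index(drop=True)
    for d in datasets[1:]:
        other = d.index[keys].reset_index(drop=True)
        if len(other) != len(ref) or not ref.equals(other):
            raise CorrespondenceError(
                f"subject {d.subject} rows do not correspond to subject "
                f"{datasets[0].subject} on (class, phrase, repeat, frame)")


def equalize_dataset(datasets: list[SubjectData]) -> list[SubjectData]:
    """Equalise clip counts and clip lengths across subjects.

    Clips are ordered repeat-major (repeat, class, phrase), so dropping from
    the end of the clip list removes the highest repeats — the only drop order
    that preserves (class, phrase, repeat) correspondence across subjects.
    All remaining clips are truncated to the globally shortest clip length.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 subjects")

    per_subject_clips = []
    for d in datasets:
        idx = d.index.reset_index(drop=True)
        order_keys = [k for k in ("repeat", "class", "phrase") if k in idx.columns]
        clip_order = (idx.drop_duplicates("clip_id")
                      .sort_values(order_keys, kind="stable")["clip_id"].tolist())
        per_subject_clips.append(clip_order)

    n_keep = min(len(c) for c in per_subject_clips)
    if n_keep == 0:
        raise ValueError("empty intersection of clips")
    min_len = min(
        int((d.index["clip_id"] == cid).sum())
        for d, clips in zip(datasets, per_subject_clips)
        for cid in clips[:n_keep])

    out = []
    for d, clips in zip(datasets, per_subject_clips):
        keep_ids = clips[:n_keep]
        idx = d.index.reset_index(drop=True)
        take = []
        for cid in keep_ids:
            rows = np.flatnonzero((idx["clip_id"] == cid).to_numpy())
            take.extend(rows[:min_len])
        take = np.array(take)
        new_idx = idx.iloc[take].reset_index(drop=True)
        # canonical row order for cross-subject correspondence
        sort_cols = [new_idx["frame"], new_idx["repeat"], new_idx["phrase"],
                     new_idx["class"].astype("category").cat.codes]
        if "clip_type" in new_idx.columns:
            sort_cols.append(new_idx["clip_type"].astype("category").cat.codes)
        order = np.lexsort(sort_cols)
        out.append(SubjectData(subject=d.subject,
                               samples=d.samples[take][order],
                               index=new_idx.iloc[order].reset_index(drop=True)))
    _assert_correspondence(out)
    return out


# ---------------------------------------------------------------------------
# Two-stage group alignment
# ---------------------------------------------------------------------------

def two_stage_group_align(subject_arrays: list[np.ndarray]
                          ) -> tuple[list[ProcrustesTransform], np.ndarray]:
    """Two-stage hyperalignment of corresponding sample matrices.

    Stage 1 grows a running average: the second subject is aligned to the
    first and the average updated; each further subject is aligned to the
    current average, which is then updated (unweighted mean of aligned
    datasets). Stage 2 refits every subject's transform to the final stage-1
    average. Returns the stage-2 transforms and the stage-1 average.
    """
    if len(subject_arrays) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = {a.shape for a in subject_arrays}
    if len(shapes) != 1:
        raise CorrespondenceError(f"subjects disagree in shape: {shapes}")

    aligned = [np.asarray(subject_arrays[0], dtype=np.float64)]
    average = aligned[0].copy()
    for X in subject_arrays[1:]:
        T = procrustes_fit(X, average)
        aligned.append(T.apply(X))
        average = np.mean(aligned, axis=0)

    transforms = [procrustes_fit(X, average) for X in subject_arrays]
    return transforms, average


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class NestedFoldSpec:
    outer_index: int
    outer_train_phrases: tuple[int, ...]
    outer_test_phrases: tuple[int, int]
    inner_index: int
    test_subject: str
    train_phrase: int
    test_phrase: int


def make_nested_folds(subjects, phrase_ids, rng: np.random.Generator | None = None
                      ) -> list[NestedFoldSpec]:
    """Outer 5-fold leave-two-phrases-out x inner (n_subjects x 2) folds.

    Phrases are paired in sorted order by default ((1,2), (3,4), ...); pass a
    seeded Generator for random pairing. Each inner fold trains on one phrase
    of the held-out pair in all-but-one subject and tests on the other phrase
    in the remaining subject.
    """
    subjects = list(subjects)
    phrase_ids = sorted(phrase_ids)
    if len(phrase_ids) % 2 != 0:
        raise ValueError("need an even number of phrases to form pairs")
    order = np.array(phrase_ids)
    if rng is not None:
        order = rng.permutation(order)
    pairs = [tuple(sorted(order[i:i + 2])) for i in range(0, len(order), 2)]

    folds = []
    for oi, pair in enumerate(pairs):
        train_phrases = tuple(p for p in phrase_ids if p not in pair)
        ii = 0
        for subj in subjects:
            for p_train, p_test in (pair, pair[::-1]):
                folds.append(NestedFoldSpec(
                    outer_index=oi, outer_train_phrases=train_phrases,
                    outer_test_phrases=pair, inner_index=ii,
                    test_subject=subj, train_phrase=p_train,
                    test_phrase=p_test))
                ii += 1
    return folds


def run_cross_subject_cv(datasets: list[SubjectData], *, use_pca: bool = False,
                         threshold: float = 0.90,
                         max_components: int | None = None,
                         ridge: float = 0.0,
                         zscore_mode: str = "independent",
                         labels_order=("positive", "negative"),
                         rng: np.random.Generator | None = None) -> CvResult:
    """Cross-subject valence classification under nested cross-validation.

    Per outer fold, the per-subject embeddings (if requested) and Procrustes
    alignments are fitted on outer-training phrases only and applied to the
    outer-test phrases; per inner fold, the LDA is fitted on one phrase per
    class in all-but-one subject and tested on the other phrase in the
    held-out subject. Returns the 30 fold accuracies (3 subjects) and the
    mean confusion matrix.
    """
    datasets = equalize_dataset(datasets)
    subjects = [d.subject for d in datasets]
    phrase_ids = sorted(datasets[0].index["phrase"].unique().tolist())
    folds = make_nested_folds(subjects, phrase_ids, rng=rng)

    accs, confs, fold_specs = [], [], []
    for oi in sorted({f.outer_index for f in folds}):
        outer = [f for f in folds if f.outer_index == oi]
        pair = outer[0].outer_test_phrases
        idx0 = datasets[0].index
        tr_mask = ~idx0["phrase"].isin(pair).to_numpy()
        te_mask = idx0["phrase"].isin(pair).to_numpy()

        if use_pca:
            models, _ = face_space.fit_common_embedding(
                [d.samples[tr_mask] for d in datasets], threshold,
                max_components=max_components)
            train_coords = [face_space.transform(m, d.samples[tr_mask])
                            for m, d in zip(models, datasets)]
            test_coords = [face_space.transform(m, d.samples[te_mask])
                           for m, d in zip(models, datasets)]
        else:
            train_coords = [d.samples[tr_mask].astype(np.float64)
                            for d in datasets]
            test_coords = [d.samples[te_mask].astype(np.float64)
                           for d in datasets]

        transforms, _ = two_stage_group_align(train_coords)
        test_aligned = [T.apply(X) for T, X in zip(transforms, test_coords)]

        te_idx = idx0.loc[te_mask].reset_index(drop=True)
        y_te = te_idx["class"].to_numpy()
        for f in outer:
            s_test = subjects.index(f.test_subject)
            tr_rows = (te_idx["phrase"] == f.train_phrase).to_numpy()
            te_rows = (te_idx["phrase"] == f.test_phrase).to_numpy()
            Xtr = np.concatenate([test_aligned[s][tr_rows]
                                  for s in range(len(subjects)) if s != s_test])
            ytr = np.concatenate([y_te[tr_rows]
                                  for s in range(len(subjects)) if s != s_test])
            Xte = test_aligned[s_test][te_rows]
            yte = y_te[te_rows]
            Ztr, Zte, _ = zscore_split(Xtr, Xte, mode=zscore_mode)
            lda = fit_lda(Ztr, ytr, ridge=ridge)
            pred = lda.predict(Zte)
            accs.append(float(np.mean(pred == yte)))
            cm, _ = summarize_confusion(pred, yte, labels=labels_order)
            confs.append(cm)
            fold_specs.append(f)

    return CvResult(fold_accuracies=np.array(accs), fold_confusions=confs,
                    mean_confusion=np.mean(confs, axis=0), folds=fold_specs)
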