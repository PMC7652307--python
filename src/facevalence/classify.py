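"""Within-subject valence classification with LDA under leave-one-phrase-out
cross-validation.

Samples are individual frames concatenated across clips. Each fold holds out
every repeat of one phrase per valence class, so successful classification
must generalise beyond phrase idiosyncrasies. Within each fold, training and
test sets are z-scored independently along each feature dimension (each set
with its own means and SDs — a leakage-free normalisation; a conventional
train-fitted scaler is available for sensitivity analysis), and a linear
discriminant is fitted to the training set only. For the image pipeline the
PCA embedding is likewise refitted on the training frames of each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import face_space


@dataclass
class FoldSpec:
    fold_index: int
    held_out_phrase: int
    train_clip_ids: list[str]
    test_clip_ids: list[str]


def make_lopo_folds(manifest: pd.DataFrame) -> list[FoldSpec]:
    """Leave-one-phrase-out folds: one fold per phrase index, holding out all
    clips (all repeats) of that phrase in *both* classes."""
    by_class = manifest.groupby("class")["phrase"].agg(lambda s: sorted(set(s)))
    phrase_sets = {k: tuple(v) for k, v in by_class.items()}
    if len(set(phrase_sets.values())) != 1:
        raise ValueError(f"classes have unequal phrase sets: {phrase_sets}")
    phrases = next(iter(phrase_sets.values()))
    folds = []
    for i, p in enumerate(phrases):
        test = manifest.loc[manifest["phrase"] == p, "clip_id"].tolist()
        train = manifest.loc[manifest["phrase"] != p, "clip_id"].tolist()
        folds.append(FoldSpec(fold_index=i, held_out_phrase=p,
                              train_clip_ids=train, test_clip_ids=test))
    return folds


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScaler:
    """Per-feature standardisation; zero-variance features are masked and map
    to 0 (and back to their mean on inversion)."""

    mean_: np.ndarray
    scale_: np.ndarray
    mask_: np.ndarray  # True where the feature had zero variance

    @classmethod
    def fit(cls, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            raise ValueError("cannot fit a scaler to an empty set")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        mask = sd <= 1e-12
        scale = np.where(mask, 1.0, sd)
        return cls(mean_=mean, scale_=scale, mask_=mask)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        Z[..., self.mask_] = 0.0
        return Z

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        X = np.asarray(Z, dtype=np.float64) * self.scale_ + self.mean_
        X[..., self.mask_] = self.mean_[self.mask_]
        return X


def zscore_split(train: np.ndarray, test: np.ndarray,
                 mode: str = "independent"
                 ) -> tuple[np.ndarray, np.ndarray, tuple[ZScaler, ZScaler]]:
    """Standardise train and test sets.

    mode="independent" (the fidelity default) z-scores each set with its own
    statistics; mode="train" applies the train-fitted scaler to both sets.
    """
    train_scaler = ZScaler.fit(train)
    if mode == "independent":
        test_scaler = ZScaler.fit(test)
    elif mode == "train":
        test_scaler = train_scaler
    else:
        raise ValueError("mode must be 'independent' or 'train'")
    return train_scaler.transform(train), test_scaler.transform(test), \
        (train_scaler, test_scaler)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Two-class linear discriminant.

    The weight vector solves (pooled within-class covariance) w = mu1 - mu0,
    with classes in sorted label order; the intercept places the boundary at
    the midpoint of the projected centroids (equal priors). Score ties are
    broken deterministically toward the first sorted label.
    """

    classes_: tuple
    means_: np.ndarray      # (2, D)
    weights_: np.ndarray    # (D,)
    intercept_: float
    ridge: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # score > 0 -> second class; ties (score == 0) -> first sorted class
        return np.where(scores > 0, self.classes_[1], self.classes_[0])


def fit_lda(train_coords: np.ndarray, labels, ridge: float = 0.0) -> LdaModel:
    X = np.asarray(train_coords, dtype=np.float64)
    y = np.asarray(labels)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 samples")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc = np.concatenate([X0 - mu0, X1 - mu1], axis=0)
    n = X.shape[0]
    Sw = (Xc.T @ Xc) / (n - 2)
    if ridge > 0:
        Sw = Sw + ridge * np.eye(Sw.shape[0])
    try:
        c, low = linalg.cho_factor(Sw)
        w = linalg.cho_solve((c, low), mu1 - mu0)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-class covariance is singular; pass ridge > 0 "
            "to regularise") from exc
    if not np.isfinite(w).all():
        raise ValueError("non-finite LDA weights; pass ridge > 0 to regularise")
    intercept = -float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(classes_=classes, means_=np.stack([mu0, mu1]),
                    weights_=w, intercept_=intercept, ridge=ridge)


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

def summarize_confusion(predictions, targets, labels=None
                        ) -> tuple[np.ndarray, float]:
    """Row-normalised 2x2 confusion matrix (rows = true class) and accuracy
    as the mean of the diagonal entries."""
    pred = np.asarray(predictions)
    true = np.asarray(targets)
    if pred.shape != true.shape:
        raise ValueError("predictions and targets must have equal length")
    if labels is None:
        labels = sorted(np.unique(true).tolist())
    labels = list(labels)
    unseen = set(pred.tolist()) - set(labels)
    if unseen:
        raise ValueError(f"predictions contain unseen labels: {sorted(unseen)}")
    cm = np.zeros((2, 2))
    for i, ti in enumerate(labels):
        row_mask = true == ti
        if row_mask.sum() == 0:
            raise ValueError(f"no samples with true label {ti!r}")
        for j, pj in enumerate(labels):
            cm[i, j] = np.mean(pred[row_mask] == pj)
    return cm, float(np.mean(np.diag(cm)))


# ---------------------------------------------------------------------------
# Within-subject cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    fold_accuracies: np.ndarray           # proportion-correct per fold
    fold_confusions: list[np.ndarray]
    mean_confusion: np.ndarray
    folds: list[FoldSpec]
    clip_accuracies: np.ndarray | None = None  # optional majority-vote report
    retained_components: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def run_within_subject_cv(samples: np.ndarray, clip_ids, manifest: pd.DataFrame,
                          *, use_pca: bool = False, threshold: float = 0.90,
                          max_components: int | None = None,
                          ridge: float = 0.0,
                          zscore_mode: str = "independent",
                          labels_order=("positive", "negative")) -> CvResult:
    """Leave-one-phrase-out LDA classification of valence.

    ``samples`` is the (n_frames_total, D) matrix (flattened 5-channel
    registered frames, or feature-table columns); ``clip_ids`` maps each row
    to its clip; ``manifest`` supplies phrase and class per clip. With
    ``use_pca`` the embedding is refitted per fold on training frames only.
    Accuracy is frame-level proportion correct; a clip-level majority-vote
    summary is also reported.
    """
    samples = np.asarray(samples)
    clip_ids = np.asarray(clip_ids)
    if samples.shape[0] != clip_ids.shape[0]:
        raise ValueError("samples and clip_ids disagree in length")
    cls_of = dict(zip(manifest["clip_id"], manifest["class"]))
    y = np.array([cls_of[c] for c in clip_ids])

    folds = make_lopo_folds(manifest)
    accs, confs, clip_accs, ks = [], [], [], []
    for fold in folds:
        tr = np.isin(clip_ids, fold.train_clip_ids)
        te = np.isin(clip_ids, fold.test_clip_ids)
        Xtr, Xte = samples[tr], samples[te]
        if use_pca:
            model, Xtr, Xte = face_space.fit_cv_embedding(
                Xtr, Xte, threshold,
                train_idx=np.flatnonzero(tr), test_idx=np.flatnonzero(te),
                max_components=max_components)
            ks.append(model.k)
        Ztr, Zte, _ = zscore_split(Xtr, Xte, mode=zscore_mode)
        lda = fit_lda(Ztr, y[tr], ridge=ridge)
        pred = lda.predict(Zte)
        accs.append(float(np.mean(pred == y[te])))
        cm, _ = summarize_confusion(pred, y[te], labels=labels_order)
        confs.append(cm)
        # clip-level majority vote (auxiliary summary, not the primary metric)
        test_ids = clip_ids[te]
        votes = []
        for cid in fold.test_clip_ids:
            m = test_ids == cid
            if m.sum() == 0:
                continue
            frac = np.mean(pred[m] == cls_of[cid])
            votes.append(1.0 if frac > 0.5 else 0.0)
        clip_accs.append(float(np.mean(votes)))
    return CvResult(fold_accuracies=np.array(accs), fold_confusions=confs,
                    mean_confusion=np.mean(confs, axis=0), folds=folds,
                    clip_accuracies=np.array(clip_accs),
                    retained_components=ks)
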