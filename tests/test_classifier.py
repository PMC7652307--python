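"""Valence classifier: fold construction, z-scoring, LDA correctness,
confusion summaries, chance calibration and signal recovery."""

import numpy as np
import pandas as pd
import pytest

from facevalence import classify as cl
from facevalence import io_formats as io
from facevalence.synthetic import (
    DatasetSpec,
    generate_dataset,
    generate_feature_table,
)

FEATURE_COLS = list(io.AU_COLUMNS) + list(io.POSE_COLUMNS)


def _feature_cv(spec, effect_size, seed=None, **kw):
    _, manifest = generate_dataset(spec, render=False)
    ft = generate_feature_table(spec, manifest, seed=seed,
                                effect_size=effect_size)
    X = ft[FEATURE_COLS].to_numpy()
    return cl.run_within_subject_cv(X, ft["clip_id"].to_numpy(), manifest, **kw)


class TestFolds:
    @pytest.mark.parametrize("phrases,expected", [(10, 10), (2, 2)])
    def test_one_fold_per_phrase(self, phrases, expected):
        spec = DatasetSpec(n_subjects=1, phrases_per_class=phrases,
                           repeats_per_subject=(2,), clip_types=("prefix",))
        _, manifest = generate_dataset(spec, render=False)
        assert len(cl.make_lopo_folds(manifest)) == expected

    def test_each_clip_tested_once_trained_elsewhere(self):
        spec = DatasetSpec(n_subjects=1, phrases_per_class=4,
                           repeats_per_subject=(3,), clip_types=("prefix",))
        _, manifest = generate_dataset(spec, render=False)
        folds = cl.make_lopo_folds(manifest)
        test_counts = {c: 0 for c in manifest["clip_id"]}
        for fold in folds:
            assert not set(fold.train_clip_ids) & set(fold.test_clip_ids)
            for c in fold.test_clip_ids:
                test_counts[c] += 1
        assert all(v == 1 for v in test_counts.values())

    def test_unequal_phrase_sets_rejected(self):
        manifest = pd.DataFrame({
            "clip_id": ["a", "b", "c"], "phrase": [1, 2, 1],
            "class": ["positive", "positive", "negative"]})
        with pytest.raises(ValueError, match="phrase"):
            cl.make_lopo_folds(manifest)


class TestZScaler:
    def test_each_split_standardised_independently(self, rng):
        train = rng.normal(5, 3, (50, 4))
        test = rng.normal(-2, 0.5, (20, 4))
        ztr, zte, _ = cl.zscore_split(train, test)
        for Z in (ztr, zte):
            assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
            assert np.allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_train_mode_shares_the_scaler(self, rng):
        train = rng.normal(5, 3, (50, 4))
        test = rng.normal(5, 3, (20, 4))
        _, zte, (str_, ste_) = cl.zscore_split(train, test, mode="train")
        assert str_ is ste_
        assert not np.allclose(zte.mean(axis=0), 0, atol=1e-6)

    def test_constant_feature_maps_to_zero_and_back(self, rng):
        X = rng.normal(0, 1, (30, 3))
        X[:, 1] = 7.0
        scaler = cl.ZScaler.fit(X)
        Z = scaler.transform(X)
        assert np.all(Z[:, 1] == 0)
        assert np.allclose(scaler.inverse_transform(Z), X)

    def test_zscore_is_idempotent(self, rng):
        X = rng.normal(3, 2, (40, 5))
        Z1 = cl.ZScaler.fit(X).transform(X)
        Z2 = cl.ZScaler.fit(Z1).transform(Z1)
        assert np.allclose(Z1, Z2, atol=1e-9)


class TestLda:
    def test_hand_fixture_matches_closed_form(self):
        # 4 points/class, diagonal pooled covariance (1/3, 1/3):
        # w = Sw^-1 (mu1 - mu0) = 3 * (3, 0) = (9, 0); boundary at midpoint
        X = np.array([[1., 0], [2, 0], [1, 1], [2, 1],
                      [4, 0], [5, 0], [4, 1], [5, 1]])
        y = np.array(["a"] * 4 + ["b"] * 4)
        m = cl.fit_lda(X, y)
        np.testing.assert_allclose(m.weights_, [9.0, 0.0], atol=1e-10)
        assert m.intercept_ == pytest.approx(-27.0)
        assert list(m.predict([[2.9, 0.5], [3.1, 0.5]])) == ["a", "b"]

    def test_gaussian_classes_recover_direction(self):
        rng = np.random.default_rng(99)
        X = np.concatenate([rng.normal(-2, 1, (500, 2)) * [1, 1] + [0, 0],
                            rng.normal(2, 1, (500, 2)) * [1, 1] + [0, 0]])
        X[:500, 1] = rng.normal(0, 1, 500)
        X[500:, 1] = rng.normal(0, 1, 500)
        y = np.array(["neg"] * 500 + ["pos"] * 500)
        m = cl.fit_lda(X, y)
        u = m.weights_ / np.linalg.norm(m.weights_)
        angle = np.degrees(np.arccos(abs(u[0])))
        assert angle < 5
        assert np.mean(m.predict(X) == y) > 0.97

    def test_label_swap_negates_weights(self, rng):
        X = rng.normal(0, 1, (40, 3))
        X[:20] += 1.5
        y = np.array(["a"] * 20 + ["b"] * 20)
        y_swapped = np.where(y == "a", "b", "a")
        m1 = cl.fit_lda(X, y)
        m2 = cl.fit_lda(X, y_swapped)
        np.testing.assert_allclose(m1.weights_, -m2.weights_, rtol=1e-9)
        assert np.all((m1.predict(X) == "a") == (m2.predict(X) == "b"))

    def test_matches_sklearn_lsqr_direction(self, rng):
        # independent implementation as oracle for the weight direction
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = rng.normal(0, 1, (200, 5))
        X[:100, 0] += 2.0
        y = np.array(["a"] * 100 + ["b"] * 100)
        ours = cl.fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        cos = np.dot(ours.weights_, sk.coef_[0]) / (
            np.linalg.norm(ours.weights_) * np.linalg.norm(sk.coef_[0]))
        assert cos == pytest.approx(1.0, abs=1e-6)
        assert np.mean(ours.predict(X) == sk.predict(X)) == 1.0

    def test_singular_covariance_advises_ridge(self):
        X = np.zeros((10, 3))
        X[:5, 0] = 1.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="ridge"):
            cl.fit_lda(X, y)
        cl.fit_lda(X, y, ridge=1e-6)  # regularised fit succeeds


class TestConfusion:
    def test_all_correct_is_identity(self):
        cm, acc = cl.summarize_confusion(["p", "n", "p"], ["p", "n", "p"],
                                         labels=["p", "n"])
        assert np.array_equal(cm, np.eye(2))
        assert acc == 1.0

    def test_all_wrong_is_antidiagonal(self):
        cm, acc = cl.summarize_confusion(["n", "p"], ["p", "n"],
                                         labels=["p", "n"])
        assert np.array_equal(cm, [[0, 1], [1, 0]])
        assert acc == 0.0

    def test_hand_counted_proportions(self):
        true = ["GN"] * 4 + ["ISTS"] * 4
        pred = ["GN", "GN", "GN", "ISTS", "ISTS", "ISTS", "GN", "GN"]
        cm, acc = cl.summarize_confusion(pred, true, labels=["GN", "ISTS"])
        np.testing.assert_allclose(cm, [[0.75, 0.25], [0.5, 0.5]])
        assert acc == pytest.approx(0.625)

    def test_unseen_prediction_label_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            cl.summarize_confusion(["x"], ["p"], labels=["p", "n"])


class TestWithinSubjectCv:
    SPEC = DatasetSpec(n_subjects=1, phrases_per_class=5,
                       repeats_per_subject=(4,), clip_types=("prefix",),
                       n_frames_prefix=6, seed=31)

    def test_chance_calibration_under_null(self):
        # 20 replicate seeds with zero injected effect: mean accuracy must sit
        # inside the 99% normal band around 0.5, with the held-out phrase pair
        # as the unit of independence
        means = [
            _feature_cv(self.SPEC.replace(seed=1000 + s), 0.0).mean_accuracy
            for s in range(20)]
        grand = float(np.mean(means))
        n_units = 20 * 2 * self.SPEC.phrases_per_class
        half_width = 2.58 * 0.5 / np.sqrt(n_units)
        assert abs(grand - 0.5) < half_width

    def test_accuracy_monotone_in_effect_size(self):
        grid = [0.0, 1.0, 2.5, 5.0]
        means = []
        for effect in grid:
            accs = [
                _feature_cv(self.SPEC.replace(seed=500 + s),
                            effect).mean_accuracy
                for s in range(6)]
            means.append(np.mean(accs))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > 0.75  # frame-level ceiling: early frames sit at
        # the foot of the expression ramp and carry almost no signal

    def test_perfectly_separable_features_classify_exactly(self):
        # stub representation carrying the label directly: identity
        # confusion matrix and accuracy 1.0 through the whole CV machinery
        _, manifest = generate_dataset(self.SPEC, render=False)
        rows = []
        for _, r in manifest.iterrows():
            sign = 1.0 if r["class"] == "positive" else -1.0
            for t in range(int(r["n_frames"])):
                rows.append((r["clip_id"], sign))
        clip_ids = np.array([c for c, _ in rows])
        X = np.array([[v] for _, v in rows]) + \
            np.random.default_rng(0).normal(0, 0.01, (len(rows), 1))
        res = cl.run_within_subject_cv(X, clip_ids, manifest)
        assert res.mean_accuracy == 1.0
        assert np.array_equal(res.mean_confusion, np.eye(2))

    def test_embedding_path_has_no_leakage(self, rng):
        # perturbing test-fold samples must leave per-fold accuracy of the
        # *other* folds untouched and the embedding identical
        from facevalence import face_space as fs
        spec = self.SPEC
        _, manifest = generate_dataset(spec, render=False)
        ft = generate_feature_table(spec, manifest, effect_size=2.0)
        X = ft[FEATURE_COLS].to_numpy()
        clip_ids = ft["clip_id"].to_numpy()
        folds = cl.make_lopo_folds(manifest)
        tr = np.isin(clip_ids, folds[0].train_clip_ids)
        te = ~tr
        m1, _, _ = fs.fit_cv_embedding(X[tr], X[te], 0.9)
        m2, _, _ = fs.fit_cv_embedding(X[tr], X[te] * 3 + 7, 0.9)
        assert np.array_equal(m1.components_, m2.components_)
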