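"""Hyperalignment: Procrustes exactness, dataset equalisation, two-stage
group alignment, nested fold construction and cross-subject classification."""

import numpy as np
import pandas as pd
import pytest

from facevalence import classify as cl
from facevalence import hyperalign as ha
from facevalence.synthetic import DatasetSpec, generate_embedded_subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


def _random_rotation(rng, k):
    R, _ = np.linalg.qr(rng.standard_normal((k, k)))
    return R


class TestProcrustes:
    def test_constructed_similarity_recovered_exactly(self, rng):
        X = rng.standard_normal((60, 6))
        R = _random_rotation(rng, 6)
        t = rng.standard_normal(6)
        Y = 1.7 * X @ R + t
        T = ha.procrustes_fit(X, Y)
        assert T.scale == pytest.approx(1.7, abs=1e-8)
        np.testing.assert_allclose(T.rotation, R, atol=1e-8)
        np.testing.assert_allclose(T.translation, t, atol=1e-8)
        np.testing.assert_allclose(T.apply(X), Y, atol=1e-8)

    def test_identical_sets_give_identity_transform(self, rng):
        X = rng.standard_normal((30, 4))
        T = ha.procrustes_fit(X, X)
        np.testing.assert_allclose(T.rotation, np.eye(4), atol=1e-8)
        assert T.scale == pytest.approx(1.0)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-8)

    def test_reflection_recovered_with_negative_determinant(self, rng):
        X = rng.standard_normal((40, 3))
        F = np.diag([-1.0, 1.0, 1.0])
        T = ha.procrustes_fit(X, X @ F)
        assert np.linalg.det(T.rotation) == pytest.approx(-1.0, abs=1e-8)
        np.testing.assert_allclose(T.apply(X), X @ F, atol=1e-8)

    def test_residual_never_worse_than_identity(self, rng):
        X = rng.standard_normal((50, 5))
        Y = X + rng.normal(0, 0.5, X.shape)
        T = ha.procrustes_fit(X, Y)
        assert ((T.apply(X) - Y) ** 2).sum() <= ((X - Y) ** 2).sum() + 1e-9

    def test_inverse_round_trips(self, rng):
        X = rng.standard_normal((20, 4))
        T = ha.procrustes_fit(X, 2.0 * X @ _random_rotation(rng, 4) + 1.0)
        np.testing.assert_allclose(T.inverse().apply(T.apply(X)), X,
                                   atol=1e-8)


def _subject_data(rng, subject, n_clips_per_cell, n_frames, k=4, extra=0):
    """Synthetic SubjectData with 2 phrases x 2 classes x repeats."""
    rows, X = [], []
    for repeat in range(1, n_clips_per_cell + 1 + extra):
        for cls in ("negative", "positive"):
            for phrase in (1, 2):
                if repeat > n_clips_per_cell and not (
                        cls == "positive" and phrase == 2):
                    continue
                cid = f"{subject}_{cls}_p{phrase}_r{repeat}"
                for t in range(n_frames):
                    rows.append({"clip_id": cid, "phrase": phrase,
                                 "class": cls, "repeat": repeat, "frame": t})
                    X.append(rng.standard_normal(k))
    return ha.SubjectData(subject=subject, samples=np.array(X),
                          index=pd.DataFrame(rows))


class TestEqualize:
    def test_extra_clips_dropped_to_common_count(self, rng):
        d1 = _subject_data(rng, "s1", 3, 5)
        d2 = _subject_data(rng, "s2", 3, 5)
        d3 = _subject_data(rng, "s3", 3, 5, extra=1)  # one extra repeat clip
        out = ha.equalize_dataset([d1, d2, d3])
        counts = [len(d.index.drop_duplicates("clip_id")) for d in out]
        assert counts == [12, 12, 12]

    def test_already_equal_is_noop_in_content(self, rng):
        d1 = _subject_data(rng, "s1", 2, 4)
        d2 = _subject_data(rng, "s2", 2, 4)
        out = ha.equalize_dataset([d1, d2])
        assert out[0].samples.shape == d1.samples.shape
        assert set(out[0].index["clip_id"]) == set(d1.index["clip_id"])

    def test_clips_truncated_to_shortest(self, rng):
        d1 = _subject_data(rng, "s1", 2, 6)
        d2 = _subject_data(rng, "s2", 2, 4)
        out = ha.equalize_dataset([d1, d2])
        for d in out:
            assert d.index.groupby("clip_id")["frame"].count().eq(4).all()
            assert d.index["frame"].max() == 3

    def test_rows_correspond_after_equalisation(self, rng):
        out = ha.equalize_dataset([_subject_data(rng, "s1", 2, 4),
                                   _subject_data(rng, "s2", 2, 5)])
        a = out[0].index[["class", "phrase", "repeat", "frame"]]
        b = out[1].index[["class", "phrase", "repeat", "frame"]]
        pd.testing.assert_frame_equal(a, b)


class TestGroupAlign:
    def test_identical_datasets_align_to_identity(self, rng):
        X = rng.standard_normal((40, 5))
        transforms, avg = ha.two_stage_group_align([X, X.copy(), X.copy()])
        for T in transforms:
            np.testing.assert_allclose(T.rotation, np.eye(5), atol=1e-8)
            assert T.scale == pytest.approx(1.0)
        np.testing.assert_allclose(avg, X, atol=1e-8)

    def test_orthogonal_copies_collapse_after_alignment(self, rng):
        X = rng.standard_normal((50, 6))
        copies = [X] + [
            s * X @ _random_rotation(rng, 6) + rng.standard_normal(6)
            for s in (0.5, 2.0)]
        transforms, _ = ha.two_stage_group_align(copies)
        aligned = [T.apply(C) for T, C in zip(transforms, copies)]
        scale = np.abs(aligned[0]).mean()
        for other in aligned[1:]:
            assert np.abs(aligned[0] - other).mean() < 1e-6 * scale

    def test_subject_order_changes_average_not_distances(self, rng):
        X = rng.standard_normal((30, 4))
        copies = [X, 1.5 * X @ _random_rotation(rng, 4),
                  0.7 * X @ _random_rotation(rng, 4) + 2.0]
        t_fwd, _ = ha.two_stage_group_align(copies)
        t_rev, _ = ha.two_stage_group_align(copies[::-1])
        def pairwise(aligned):
            return [np.abs(a - b).mean()
                    for i, a in enumerate(aligned)
                    for b in aligned[i + 1:]]
        d_fwd = pairwise([T.apply(C) for T, C in zip(t_fwd, copies)])
        d_rev = pairwise([T.apply(C) for T, C in zip(t_rev, copies[::-1])])
        assert np.allclose(sorted(d_fwd), sorted(d_rev), atol=1e-8)


class TestNestedFolds:
    def test_default_scheme_yields_30_folds(self):
        folds = ha.make_nested_folds(["s1", "s2", "s3"], range(1, 11))
        assert len(folds) == 30
        assert len({f.outer_index for f in folds}) == 5

    def test_every_phrase_held_out_exactly_once(self):
        folds = ha.make_nested_folds(["s1", "s2", "s3"], range(1, 11))
        held = [p for oi in range(5)
                for p in next(f for f in folds
                              if f.outer_index == oi).outer_test_phrases]
        assert sorted(held) == list(range(1, 11))

    def test_inner_train_excludes_test_subject_and_phrase(self):
        for f in ha.make_nested_folds(["s1", "s2", "s3"], range(1, 11)):
            assert f.train_phrase != f.test_phrase
            assert {f.train_phrase, f.test_phrase} == set(f.outer_test_phrases)
            assert f.test_phrase in f.outer_test_phrases
            assert f.train_phrase not in f.outer_train_phrases

    def test_odd_phrase_count_rejected(self):
        with pytest.raises(ValueError):
            ha.make_nested_folds(["s1", "s2"], [1, 2, 3])


@pytest.fixture(scope="module")
def shared_signal_spec():
    return DatasetSpec(n_subjects=3, repeats_per_subject=(4, 4, 5),
                       clip_types=("prefix",), n_frames_prefix=8, seed=23)


class TestCrossSubjectCv:
    def test_shared_signal_recovered_above_chance(self, shared_signal_spec):
        datasets = generate_embedded_subjects(shared_signal_spec,
                                              effect_size=4.0)
        res = ha.run_cross_subject_cv(datasets)
        assert len(res.fold_accuracies) == 30
        assert res.mean_accuracy > 0.55
        # ... but below within-subject performance on the same data
        d0 = datasets[0]
        man = (d0.index.drop_duplicates("clip_id")
               .merge(d0.index.groupby("clip_id").size().rename("n_frames"),
                      on="clip_id"))
        within = cl.run_within_subject_cv(
            d0.samples, d0.index["clip_id"].to_numpy(), man)
        assert res.mean_accuracy < within.mean_accuracy

    def test_outer_test_perturbation_leaves_transforms_unchanged(
            self, shared_signal_spec):
        datasets = generate_embedded_subjects(shared_signal_spec,
                                              effect_size=4.0)
        eq = ha.equalize_dataset(datasets)
        pair = (1, 2)
        tr = ~eq[0].index["phrase"].isin(pair).to_numpy()
        t1, _ = ha.two_stage_group_align([d.samples[tr] for d in eq])
        # perturb what would be outer-test rows; outer-train fit unchanged
        for d in eq:
            d.samples[~tr] *= 100
        t2, _ = ha.two_stage_group_align([d.samples[tr] for d in eq])
        for a, b in zip(t1, t2):
            assert np.array_equal(a.rotation, b.rotation)
            assert a.scale == b.scale
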