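"""Folds, augmentation, class weights, task relabeling and the train loop."""

from dataclasses import replace

import numpy as np
import pytest

import scintigrade as sg
from scintigrade.preprocess import PreprocessedImage
from conftest import make_blob_images


class TestStratifiedFolds:
    def test_minority_class_spreads_four_or_five_per_fold(self):
        labels = np.repeat(np.arange(4), (991, 296, 23, 24))
        folds = sg.make_stratified_folds(labels, k=5, seed=0)
        grade3_per_fold = [np.sum(labels[f.test_ids] == 3) for f in folds]
        assert sorted(grade3_per_fold) == [4, 5, 5, 5, 5]

    def test_equal_class_splits_exactly(self):
        folds = sg.make_stratified_folds([0] * 10, k=5, seed=1)
        assert all(len(f.test_ids) == 2 for f in folds)

    def test_folds_partition_the_dataset(self):
        labels = np.repeat(np.arange(4), (40, 30, 20, 10))
        folds = sg.make_stratified_folds(labels, k=5, seed=2)
        pooled = np.concatenate([f.test_ids for f in folds])
        assert sorted(pooled) == list(range(100))
        for f in folds:
            assert set(f.train_ids).isdisjoint(f.test_ids)

    def test_reseeding_changes_membership_not_counts(self):
        labels = np.repeat(np.arange(4), (40, 30, 20, 10))
        fa = sg.make_stratified_folds(labels, k=5, seed=0)
        fb = sg.make_stratified_folds(labels, k=5, seed=1)
        assert any(set(a.test_ids) != set(b.test_ids) for a, b in zip(fa, fb))
        for a, b in zip(fa, fb):
            ca = np.bincount(labels[a.test_ids], minlength=4)
            cb = np.bincount(labels[b.test_ids], minlength=4)
            assert ca.tolist() == cb.tolist()

    def test_k_below_two_raises(self):
        with pytest.raises(ValueError, match="k"):
            sg.make_stratified_folds([0, 1, 0, 1], k=1)

    def test_underpopulated_class_degrades_with_warning(self, caplog):
        labels = [0] * 20 + [1] * 3
        with caplog.at_level("WARNING"):
            folds = sg.make_stratified_folds(labels, k=5, seed=0)
        assert "least populated" in caplog.text
        assert len(folds) == 5


class TestAugmentation:
    def test_multiplier_five_on_a_1066_image_fold_gives_5330(self):
        images = list(np.random.default_rng(0).random((1066, 16, 16)))
        aug = sg.augment_training_set(images, sg.AugmentationConfig(multiplier=5))
        assert len(aug) == 5330

    def test_multiplier_zero_gives_empty_set(self):
        images = list(np.random.default_rng(0).random((4, 16, 16)))
        assert sg.augment_training_set(images,
                                       sg.AugmentationConfig(multiplier=0)) == []

    def test_zero_ranges_reproduce_sources_exactly(self):
        rng = np.random.default_rng(1)
        images = [PreprocessedImage(rng.random((128, 128)), source_id=f"s{i}",
                                    grade=i % 4) for i in range(3)]
        cfg = sg.AugmentationConfig(shift_range=0, rotation_range=0,
                                    zoom_range=0, multiplier=2, seed=0)
        aug = sg.augment_training_set(images, cfg)
        assert len(aug) == 6
        by_id = {im.source_id: im for im in images}
        for a in aug:
            src = by_id[a.source_id.split("_aug")[0]]
            assert np.allclose(a.pixels, src.pixels, atol=1e-10)
            assert a.grade == src.grade

    def test_seeded_augmentation_is_reproducible(self):
        images = list(np.random.default_rng(2).random((5, 32, 32)))
        cfg = sg.AugmentationConfig(multiplier=3, seed=9)
        a = sg.augment_training_set(images, cfg)
        b = sg.augment_training_set(images, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sg.AugmentationConfig(shift_range=-0.1)


class TestClassWeights:
    def test_clinical_cohort_weights(self):
        labels = np.repeat(np.arange(4), (991, 296, 23, 24))
        w = sg.compute_class_weights(labels)
        assert np.allclose(w.weights, [0.337, 1.127, 14.500, 13.896], atol=1e-3)

    def test_balanced_labels_give_unit_weights(self):
        w = sg.compute_class_weights([0, 0, 1, 1, 2, 2, 3, 3])
        assert np.allclose(w.weights, 1.0)

    def test_weighted_count_identity(self):
        labels = np.repeat(np.arange(4), (991, 296, 23, 24))
        w = sg.compute_class_weights(labels)
        counts = np.bincount(labels)
        assert np.dot(w.weights, counts) == pytest.approx(len(labels), abs=1e-9)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="empty class"):
            sg.compute_class_weights([0, 0, 1], n_classes=4)


class TestTaskRelabeling:
    @pytest.mark.parametrize("task,expected", [
        ("four_class", [0, 1, 2, 3]),
        ("pos_vs_neg", [0, 0, 1, 1]),          # positive means grade >= 2
        ("grade3_vs_rest", [0, 0, 0, 1]),
    ])
    def test_task_mappings(self, task, expected):
        assert sg.relabel_for_task([0, 1, 2, 3], task).tolist() == expected

    def test_unknown_task_raises(self):
        with pytest.raises(ValueError, match="task"):
            sg.relabel_for_task([0, 1], "five_class")

    def test_out_of_range_grade_raises(self):
        with pytest.raises(ValueError, match="grades"):
            sg.relabel_for_task([0, 4], "four_class")


class TestTrainModel:
    def _tiny_handle(self, n_classes=2, size=32, seed=0):
        spec = sg.ModelSpec(family="linear", n_classes=n_classes,
                            input_shape=(size, size, 1), stem_filters=2,
                            block_filters=(2, 3, 4, 5), seed=seed)
        return sg.build_linear(spec)

    def test_all_zero_class_weights_leave_parameters_unchanged(self):
        X, y = make_blob_images(12, 2)
        handle = self._tiny_handle()
        before = handle.net.get_weights()
        weights = sg.ClassWeights(np.zeros(2))
        cfg = sg.TrainConfig(epochs=2, batch_size=4, seed=0)
        _, hist = sg.train_model(handle, X, y, weights, cfg)
        assert max(hist["loss"]) == 0.0
        for b, a in zip(before, handle.net.get_weights()):
            assert np.array_equal(b, a)

    def test_lr_history_is_non_increasing_and_floored(self):
        X, y = make_blob_images(12, 2)
        handle = self._tiny_handle(seed=1)
        cfg = sg.TrainConfig(epochs=6, batch_size=4, initial_lr=1e-4,
                             lr_patience=1, lr_factor=0.01, seed=0)
        _, hist = sg.train_model(handle, X, y, None, cfg)
        lrs = hist["lr"]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert min(lrs) >= 1e-7

    def test_empty_training_set_raises(self):
        handle = self._tiny_handle()
        with pytest.raises(ValueError, match="empty"):
            sg.train_model(handle, np.empty((0, 32, 32)), np.empty(0, int),
                           None, sg.TrainConfig(epochs=1))

    def test_learns_separable_two_class_phantoms(self):
        """On linearly separable two-grade phantoms, training accuracy
        reaches 0.95 within 10 epochs; a logistic-regression oracle on the
        mean cardiac-window intensity achieves 1.0 on the same data."""
        intervals = {0: (0.0, 0.1), 3: (1.5, 2.0)}
        images, labels, feats = [], [], []
        for i in range(24):
            grade = 3 if i % 2 else 0
            cfg = sg.PhantomConfig(seed=400 + i, hotspot_rate=0.5,
                                   grade_ratio_intervals=intervals)
            study = sg.generate_whole_body(cfg, grade)
            im = sg.preprocess_study(study)
            images.append(im.pixels)
            labels.append(0 if grade == 0 else 1)
            feats.append(im.pixels[40:90, 30:90].mean())

        from sklearn.linear_model import LogisticRegression

        oracle = LogisticRegression().fit(np.array(feats)[:, None], labels)
        assert oracle.score(np.array(feats)[:, None], labels) == 1.0

        X = sg.ZScoreNormalizer().fit_transform(np.stack(images))
        y = np.array(labels)
        spec = sg.ModelSpec(family="linear", n_classes=2, stem_filters=2,
                            block_filters=(2, 3, 4, 5), seed=0)
        handle = sg.build_linear(spec)
        cfg = sg.TrainConfig(epochs=10, batch_size=4, initial_lr=1e-3,
                             lr_factor=0.5, scaled_init=True,
                             head_init_steps=300, seed=0)
        handle, _ = sg.train_model(handle, X, y, None, cfg)
        acc = (handle.predict_proba(X.astype(np.float32)).argmax(1) == y).mean()
        assert acc >= 0.95


@pytest.fixture(scope="module")
def cv_result():
    rng = np.random.default_rng(0)
    images = [PreprocessedImage(rng.random((128, 128)), source_id=f"s{i}",
                                grade=i % 4, has_metastases=bool(i % 3 == 0))
              for i in range(16)]
    spec = sg.ModelSpec(family="linear", stem_filters=2,
                        block_filters=(2, 2, 2, 2))
    cfg = sg.TrainConfig(epochs=1, batch_size=4, seed=0)
    return images, sg.run_cross_validation(
        images, spec, "four_class",
        aug_cfg=sg.AugmentationConfig(multiplier=0),
        train_cfg=cfg, k=2, seed=0)


class TestCrossValidationPlumbing:

    def test_every_study_appears_once_in_pooled_predictions(self, cv_result):
        images, result = cv_result
        assert sorted(result.predictions["id"]) == sorted(im.source_id
                                                          for im in images)
        assert result.report.confusion.sum() == len(images)

    def test_normalization_stats_depend_only_on_the_train_fold(self, cv_result):
        images, result = cv_result
        for fold, norm in zip(result.folds, result.normalizers):
            expected = sg.ZScoreNormalizer().fit(
                [images[i] for i in fold.train_ids])
            assert np.allclose(norm.mean_, expected.mean_)
            assert np.allclose(norm.std_, expected.std_)

    def test_subgroup_sizes_sum_to_total(self, cv_result):
        _, result = cv_result
        subs = result.subgroups()
        assert subs["metastases"].n + subs["no_metastases"].n == result.report.n
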