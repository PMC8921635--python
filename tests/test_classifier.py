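"""Classifier: splitting, building, AUROC, HSV baseline, evaluation."""

import numpy as np
import pytest

from contourpro import (
    ContourDataset,
    ContourImage,
    auroc,
    build_classifier,
    evaluate,
    hsv_histogram_features,
    predict_proba,
    split_dataset,
    train_classifier,
)
from contourpro.classifier import load_classifier, save_classifier


def _tiny_dataset(n_per_group=10, seed=0, groups=("A", "B"), size=8):
    rng = np.random.default_rng(seed)
    return ContourDataset({
        g: [ContourImage(rng.random((size, size, 3)).astype(np.float32))
            for _ in range(n_per_group)]
        for g in groups
    })


class TestSplit:
    def test_85_15_per_group(self):
        ds = _tiny_dataset(n_per_group=100)
        train, val = split_dataset(ds, seed=1)
        for g in ds.group_labels:
            assert len(train.groups[g]) == 85
            assert len(val.groups[g]) == 15

    def test_disjoint_and_exhaustive(self):
        ds = _tiny_dataset(n_per_group=9)
        train, val = split_dataset(ds, seed=2)
        for g in ds.group_labels:
            ids_train = {id(im) for im in train.groups[g]}
            ids_val = {id(im) for im in val.groups[g]}
            assert not ids_train & ids_val
            assert len(ids_train | ids_val) == 9

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_tiny_dataset(), train_fraction=1.0)

    def test_too_small_group_rejected(self):
        ds = _tiny_dataset(n_per_group=1)
        with pytest.raises(ValueError):
            split_dataset(ds)

    def test_stratified_proportions(self):
        ds = _tiny_dataset(n_per_group=20)
        train, _ = split_dataset(ds, seed=3)
        sizes = {g: len(v) for g, v in train.groups.items()}
        assert len(set(sizes.values())) == 1  # equal groups stay equal


class TestBuild:
    def test_small_cnn_outputs_probabilities(self, peak_image):
        model = build_classifier("small_cnn", 128, 2, seed=0)
        probs = predict_proba(model, [peak_image])
        assert probs.shape == (1, 2)
        assert probs.sum(axis=1) == pytest.approx(1.0, abs=1e-6)

    def test_max_input_size_accepted(self):
        model = build_classifier("small_cnn", 512, 2, seed=0)
        assert model.input_size == 512

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            build_classifier("small_cnn", 64, 2)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            build_classifier("alexnet", 128, 2)

    def test_missing_pretrained_weights_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="never downloaded"):
            build_classifier("vgg16", 128, 2, pretrained=True,
                             weights_path=tmp_path / "none.npz")

    def test_deterministic_init(self, peak_image):
        p1 = predict_proba(build_classifier("small_cnn", 128, 2, seed=5), [peak_image])
        p2 = predict_proba(build_classifier("small_cnn", 128, 2, seed=5), [peak_image])
        assert np.array_equal(p1, p2)


class TestTraining:
    def test_history_reproducible_without_augmentation(self):
        ds = _tiny_dataset(n_per_group=6, size=16)

        def run():
            train, val = split_dataset(ds, seed=4)
            model = build_classifier("small_cnn", 128, 2,
                                     class_labels=["A", "B"], seed=4)
            _, hist = train_classifier(model, train, val, epochs=2, seed=4)
            return hist

        h1, h2 = run(), run()
        assert h1.train_loss == h2.train_loss
        assert h1.val_acc == h2.val_acc

    def test_history_lengths_and_ranges(self):
        ds = _tiny_dataset(n_per_group=6, size=16)
        train, val = split_dataset(ds, seed=1)
        model = build_classifier("small_cnn", 128, 2, class_labels=["A", "B"], seed=1)
        _, hist = train_classifier(model, train, val, epochs=3, seed=1, augment=True)
        assert len(hist) == 3
        assert all(0.0 <= v <= 1.0 for v in hist.val_acc + hist.train_acc + hist.auroc)

    def test_multiclass_supported(self):
        ds = _tiny_dataset(n_per_group=4, groups=("A", "B", "C"), size=16)
        train, val = split_dataset(ds, seed=0)
        model = build_classifier("small_cnn", 128, 3,
                                 class_labels=["A", "B", "C"], seed=0)
        _, hist = train_classifier(model, train, val, epochs=1, seed=0)
        assert len(hist) == 1


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestHSVFeatures:
    def test_normalized_to_unit_sum(self, peak_image):
        feats = hsv_histogram_features(peak_image)
        assert feats.shape == (512,)
        assert feats.sum() == pytest.approx(1.0)

    def test_uniform_color_single_bin(self):
        img = ContourImage(np.full((16, 16, 3), 0.25, np.float32))
        feats = hsv_histogram_features(img)
        assert (feats > 0).sum() == 1

    def test_invariant_to_pixel_permutation(self, peak_image):
        rng = np.random.default_rng(0)
        flat = peak_image.pixels.reshape(-1, 3)
        shuffled = ContourImage(
            flat[rng.permutation(len(flat))].reshape(peak_image.shape))
        assert np.allclose(hsv_histogram_features(peak_image),
                           hsv_histogram_features(shuffled))

    def test_grayscale_rejected(self):
        img = ContourImage(np.zeros((16, 16, 1), np.float32))
        with pytest.raises(ValueError):
            hsv_histogram_features(img)


class TestEvaluate:
    def test_confusion_counts_sum_to_dataset_size(self):
        ds = _tiny_dataset(n_per_group=5, size=16)
        model = build_classifier("small_cnn", 128, 2, class_labels=["A", "B"], seed=0)
        acc, confusion, au = evaluate(model, ds)
        assert sum(confusion.values()) == ds.n_images()
        assert 0.0 <= acc <= 1.0
        assert au is None or 0.0 <= au <= 1.0

    def test_unknown_group_rejected(self):
        ds = _tiny_dataset(n_per_group=5, groups=("X", "Y"), size=16)
        model = build_classifier("small_cnn", 128, 2, class_labels=["A", "B"], seed=0)
        with pytest.raises(ValueError):
            evaluate(model, ds)


def test_save_load_round_trip(tmp_path, peak_image):
    model = build_classifier("small_cnn", 128, 2, class_labels=["A", "B"], seed=7)
    save_classifier(model, tmp_path)
    loaded = load_classifier(tmp_path)
    assert np.array_equal(predict_proba(model, [peak_image]),
                          predict_proba(loaded, [peak_image]))
    assert loaded.class_labels == ["A", "B"]
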