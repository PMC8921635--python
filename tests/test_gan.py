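"""Adversarial synthesizer: determinism, losses, bookkeeping, augmentation."""

import numpy as np
import pytest

from contourpro import augment, generate_group_dataset
from contourpro.gan import (
    GANTrainingHistory,
    batch_to_images,
    gan_train_step,
    images_to_batch,
    init_gan,
    load_gan,
    save_gan,
    synthesize,
    synthesize_dataset,
    train_gan,
)


@pytest.fixture(scope="module")
def tiny_dataset(peak_group):
    return generate_group_dataset(peak_group, n=8, size=(64, 64), seed=2)


@pytest.fixture(scope="module")
def gan_state():
    return init_gan(64, seed=11)


class TestInit:
    def test_same_seed_same_first_batch(self):
        a = synthesize(init_gan(64, seed=4), n=2, seed=0)
        b = synthesize(init_gan(64, seed=4), n=2, seed=0)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_max_resolution_accepted(self):
        state = init_gan(512, seed=0)
        assert state.resolution == 512

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            init_gan(100)

    def test_small_z_rejected(self):
        with pytest.raises(ValueError):
            init_gan(64, z_dim=4)


class TestTrainStep:
    @pytest.mark.parametrize("loss_mode", ["qp", "logistic"])
    def test_one_step_updates_both_networks(self, tiny_dataset, loss_mode):
        state = init_gan(64, seed=3, loss_mode=loss_mode)
        g_before = [p.value.copy() for p in state.generator.params()]
        d_before = [p.value.copy() for p in state.discriminator.params()]
        real = images_to_batch(tiny_dataset.groups["g"][:4])
        z = np.random.default_rng(0).standard_normal((4, state.z_dim))
        state, g_loss, d_loss = gan_train_step(state, real, z)
        assert np.isfinite(g_loss) and np.isfinite(d_loss)
        assert any(not np.array_equal(a, b.value)
                   for a, b in zip(g_before, state.generator.params()))
        assert any(not np.array_equal(a, b.value)
                   for a, b in zip(d_before, state.discriminator.params()))
        assert state.iteration == 1

    def test_batch_too_small_rejected(self, gan_state):
        real = np.zeros((1, 3, 64, 64), np.float32)
        with pytest.raises(ValueError):
            gan_train_step(gan_state, real, np.zeros((1, gan_state.z_dim)))


class TestSynthesize:
    def test_deterministic_given_seed(self, gan_state):
        a = synthesize(gan_state, n=3, seed=5)
        b = synthesize(gan_state, n=3, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)

    def test_outputs_bounded(self, gan_state):
        for img in synthesize(gan_state, n=2, seed=1):
            assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
            assert img.shape == (64, 64, 3)

    def test_zero_z_scale_collapses_to_g0(self, gan_state):
        imgs = synthesize(gan_state, n=3, z_scale=0.0, seed=9)
        assert np.array_equal(imgs[0].pixels, imgs[1].pixels)
        assert np.array_equal(imgs[0].pixels, imgs[2].pixels)

    def test_n_zero_empty(self, gan_state):
        assert synthesize(gan_state, n=0) == []

    def test_z_scale_range_enforced(self, gan_state):
        with pytest.raises(ValueError):
            synthesize(gan_state, n=1, z_scale=3.0)


class TestSynthesizeDataset:
    def test_default_multiplier_is_ten(self, gan_state):
        ds = synthesize_dataset(gan_state, source_count=3, seed=0)
        assert ds.n_images() == 30
        assert ds.group_labels == ["synthetic"]

    def test_multiplier_one(self, gan_state):
        assert synthesize_dataset(gan_state, source_count=4, multiplier=1,
                                  seed=0).n_images() == 4

    def test_outputs_pairwise_distinct(self, gan_state):
        imgs = synthesize_dataset(gan_state, source_count=3, multiplier=2,
                                  seed=2).groups["synthetic"]
        for i in range(len(imgs)):
            for j in range(i + 1, len(imgs)):
                assert np.abs(imgs[i].pixels - imgs[j].pixels).max() > 0


class TestTrainGan:
    def test_history_bookkeeping(self, tiny_dataset):
        state = init_gan(64, seed=6)
        state, hist = train_gan(state, tiny_dataset, iterations=2, fid_every=1,
                                fid_batch=4, batch_size=4)
        assert len(hist) == 2
        assert hist.iterations == [1, 2]
        assert all(np.isfinite(v) for v in hist.fid + hist.qscore)

    def test_preview_grid_written(self, tiny_dataset, tmp_path):
        state = init_gan(64, seed=6)
        train_gan(state, tiny_dataset, iterations=1, fid_every=1, fid_batch=4,
                  batch_size=4, preview_dir=tmp_path)
        assert list(tmp_path.glob("preview_*.png"))

    def test_history_rejects_non_increasing_iterations(self):
        hist = GANTrainingHistory()
        hist.append(5, 0.0, 0.0, 1.0, 0.18)
        with pytest.raises(ValueError):
            hist.append(5, 0.0, 0.0, 1.0, 0.18)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_dataset, tmp_path):
        state = init_gan(64, seed=8)
        real = images_to_batch(tiny_dataset.groups["g"][:4])
        z = np.random.default_rng(1).standard_normal((4, state.z_dim))
        state, _, _ = gan_train_step(state, real, z)
        save_gan(state, tmp_path)
        loaded = load_gan(tmp_path)
        a = synthesize(state, n=2, seed=3)
        b = synthesize(loaded, n=2, seed=3)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert loaded.iteration == state.iteration


class TestAugment:
    def test_zero_brightness_is_identity(self, peak_image):
        out = augment(peak_image, ["brightness"], {"brightness": {"delta": 0.0}})
        assert np.allclose(out.pixels, peak_image.pixels, atol=1e-7)

    def test_blur_sharpen_order_matters(self, peak_image):
        ab = augment(peak_image, ["blur", "sharpen"])
        ba = augment(peak_image, ["sharpen", "blur"])
        assert np.abs(ab.pixels - ba.pixels).max() > 1e-4

    def test_noise_reproducible_given_seed(self, peak_image):
        a = augment(peak_image, ["noise"], seed=13)
        b = augment(peak_image, ["noise"], seed=13)
        assert np.array_equal(a.pixels, b.pixels)

    def test_all_named_ops_run_and_stay_bounded(self, peak_image):
        ops = ["sharpen", "blur", "noise", "denoise", "erode", "dilate",
               "distort", "brightness", "contrast", "edge_enhance"]
        out = augment(peak_image, ops, seed=1)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_unknown_op_rejected(self, peak_image):
        with pytest.raises(ValueError):
            augment(peak_image, ["posterize"])

    def test_empty_ops_rejected(self, peak_image):
        with pytest.raises(ValueError):
            augment(peak_image, [])


def test_roundtrip_image_batch_conversion(peak_image):
    batch = images_to_batch([peak_image, peak_image])
    back = batch_to_images(batch)
    assert np.allclose(back[0].pixels, peak_image.pixels)
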