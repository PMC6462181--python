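"""Classifier architecture, training dynamics and dense-inference contracts.

The expensive contracts (dense ≡ naive sliding window, tiling
invariance) run on small crops with the reduced-width architecture; the
full-scale equivalents live in the acceptance suite.
"""

import numpy as np
import pytest

from ihcdetect.cnn_model import (
    CNNConfig,
    PatchCNN,
    TrainingConfig,
    UntrainedModelError,
    build_model,
    classify_patches,
    predict_likelihood_map,
    train,
    _softmax,
)
from ihcdetect.imaging_io import ImageMetadata, RGBImage
from ihcdetect.patch_pipeline import LabeledPatch, NEGATIVE, POSITIVE

from conftest import SMALL_CNN


def _color_patches(n_per_class, seed=0):
    """Two trivially separable color classes (brown-ish vs blue-ish)."""
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n_per_class):
        brown = np.clip(
            np.array([150, 100, 50]) + rng.normal(0, 12, (46, 46, 3)), 0, 255
        ).astype(np.uint8)
        blue = np.clip(
            np.array([90, 90, 180]) + rng.normal(0, 12, (46, 46, 3)), 0, 255
        ).astype(np.uint8)
        patches.append(LabeledPatch(pixels=brown, label=POSITIVE))
        patches.append(LabeledPatch(pixels=blue, label=NEGATIVE))
    return patches


class TestConfig:
    def test_default_stack_ends_at_4x4(self):
        assert CNNConfig().feature_size() == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(conv_channels=(32,) * 5),  # five convs
            dict(pool_after=(1,)),  # one pool
            dict(fc_sizes=(256, 3)),  # not two classes
            dict(kernel_size=9),  # receptive field exceeds the patch
        ],
    )
    def test_invalid_architectures_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CNNConfig(**kwargs)

    def test_training_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainingConfig(nesterov_momentum=1.0)


class TestBuildAndForward:
    def test_forward_probabilities_sum_to_one(self):
        model = build_model(SMALL_CNN, seed=0)
        probs = model.forward_probs(np.zeros((2, 46, 46, 3), np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_parameters(self):
        a = build_model(SMALL_CNN, seed=5)
        b = build_model(SMALL_CNN, seed=5)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_parameter_count_positive_and_finite(self):
        model = build_model(seed=0)
        assert model.n_parameters > 0
        assert all(np.isfinite(p).all() for p in model.params.values())

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(SMALL_CNN, seed=3)
        model.trained = True
        p = tmp_path / "model.npz"
        model.save(p)
        back = PatchCNN.load(p)
        assert back.trained
        assert back.config == SMALL_CNN
        for k in model.params:
            np.testing.assert_array_equal(back.params[k], model.params[k])


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        model = build_model(SMALL_CNN, seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        train(
            model,
            _color_patches(50),
            TrainingConfig(learning_rate=0.0, seed=0),
        )
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_same_seed_same_final_parameters(self):
        data = _color_patches(100)
        a = build_model(SMALL_CNN, seed=1)
        b = build_model(SMALL_CNN, seed=1)
        train(a, data, TrainingConfig(seed=2))
        train(b, data, TrainingConfig(seed=2))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_single_class_data_rejected(self):
        model = build_model(SMALL_CNN, seed=0)
        only_pos = [p for p in _color_patches(10) if p.label == POSITIVE]
        with pytest.raises(ValueError):
            train(model, only_pos, TrainingConfig(seed=0))

    def test_separable_color_classes_reach_high_train_accuracy(self):
        data = _color_patches(1000)  # 2,000 patches
        model = build_model(SMALL_CNN, seed=0)
        train(model, data, TrainingConfig(seed=0, epochs=3))
        probs = classify_patches(model, data)
        labels = np.array([p.label == POSITIVE for p in data])
        assert np.mean((probs >= 0.5) == labels) >= 0.99

    def test_loss_trend_decreases_over_the_first_epoch(self):
        data = _color_patches(1000)
        model = build_model(SMALL_CNN, seed=0)
        history = train(model, data, TrainingConfig(seed=0, batch_size=64))
        losses = np.array(history.step_losses)
        thirds = np.array_split(losses, 3)
        means = [t.mean() for t in thirds]
        assert means[0] > means[1] > means[2]


class TestClassification:
    def test_batch_size_independence(self, quick_model, small_patch_corpus):
        sample = small_patch_corpus[:40]
        a = classify_patches(quick_model, sample, batch_size=1)
        b = classify_patches(quick_model, sample, batch_size=512)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_duplicated_patch_identical_probability(self, quick_model,
                                                    small_patch_corpus):
        p = small_patch_corpus[0]
        probs = classify_patches(quick_model, [p, p])
        assert probs[0] == probs[1]

    def test_wrong_patch_size_rejected(self, quick_model):
        with pytest.raises(ValueError):
            classify_patches(quick_model, np.zeros((1, 32, 32, 3), np.uint8))

    def test_untrained_model_rejected(self):
        model = build_model(SMALL_CNN, seed=0)
        with pytest.raises(UntrainedModelError):
            classify_patches(model, np.zeros((1, 46, 46, 3), np.uint8))


class TestLikelihoodMap:
    def _naive_map(self, model, pixels):
        H, W = pixels.shape[:2]
        xf = pixels.astype(np.float64) / 255.0
        out = np.zeros((H, W))
        for cy in range(23, H - 22):
            for cx in range(23, W - 22):
                win = xf[cy - 23 : cy + 23, cx - 23 : cx + 23][None]
                logits, _ = model.forward_logits(win)
                out[cy, cx] = _softmax(logits[0, 0, 0, :])[1]
        return out

    def test_dense_inference_matches_naive_windows(self, quick_model, rng):
        px = rng.integers(0, 256, (56, 58, 3), np.uint8)
        img = RGBImage(px, ImageMetadata(image_id="crop"))
        dense = predict_likelihood_map(quick_model, img).values
        naive = self._naive_map(quick_model, px)
        np.testing.assert_allclose(dense, naive, atol=1e-4)

    def test_border_band_is_zero_and_values_in_unit_interval(
        self, quick_model, rng
    ):
        px = rng.integers(0, 256, (70, 64, 3), np.uint8)
        lmap = predict_likelihood_map(
            quick_model, RGBImage(px, ImageMetadata())
        )
        v = lmap.values
        assert v.shape == (70, 64)
        assert v[:23].max() == 0 and v[-22:].max() == 0
        assert v[:, :23].max() == 0 and v[:, -22:].max() == 0
        assert v.min() >= 0 and v.max() <= 1

    def test_tiling_does_not_change_any_value(self, quick_model, rng):
        px = rng.integers(0, 256, (120, 130, 3), np.uint8)
        img = RGBImage(px, ImageMetadata())
        whole = predict_likelihood_map(quick_model, img).values
        tiled = predict_likelihood_map(quick_model, img, tile=80, halo=23).values
        np.testing.assert_allclose(whole, tiled, atol=1e-6)

    def test_image_smaller_than_patch_rejected(self, quick_model):
        img = RGBImage(np.zeros((40, 40, 3), np.uint8), ImageMetadata())
        with pytest.raises(ValueError):
            predict_likelihood_map(quick_model, img)

    def test_halo_below_patch_half_rejected(self, quick_model, rng):
        px = rng.integers(0, 256, (100, 100, 3), np.uint8)
        with pytest.raises(ValueError):
            predict_likelihood_map(
                quick_model, RGBImage(px, ImageMetadata()), tile=60, halo=10
            )
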