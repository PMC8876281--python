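"""Desk-scale segmentation: augmentation, normalization, training protocol."""

import warnings

import numpy as np
import pytest

from pcscale import phantom
from pcscale.segtrain import (
    SegModelSpec,
    SegNet2D,
    TrainConfig,
    augment,
    evaluate_folds,
    normalize,
    predict_slices,
    train_segmenter,
    with_coords,
)
from pcscale.segtrain.nn import class_weights, softmax_cross_entropy


@pytest.fixture(scope="module")
def tiny_slices():
    images, labels, z = phantom.synthetic_slices(n=6, size=48, seed=1)
    return images, labels, z


class TestAugment:
    def test_identity_when_disabled(self, tiny_slices):
        images, labels, _ = tiny_slices
        cfg = TrainConfig(crop=48, scale_amplitude=0.0)
        im, lb = augment(images[0], labels[0], cfg, seed=0)
        assert np.array_equal(im, images[0]) and np.array_equal(lb, labels[0])

    def test_deterministic_under_seed(self, tiny_slices):
        images, labels, _ = tiny_slices
        cfg = TrainConfig(crop=40, scale_amplitude=0.1)
        a = augment(images[0], labels[0], cfg, seed=7)
        b = augment(images[0], labels[0], cfg, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_crop_shape_and_label_subset(self, tiny_slices):
        images, labels, _ = tiny_slices
        cfg = TrainConfig(crop=40, scale_amplitude=0.1)
        for seed in range(10):
            im, lb = augment(images[2], labels[2], cfg, seed=seed)
            assert im.shape == (40, 40) and lb.shape == (40, 40)
            assert set(np.unique(lb)) <= set(np.unique(labels[2])) | {0}

    def test_crop_larger_than_image_rejected(self, tiny_slices):
        images, labels, _ = tiny_slices
        with pytest.raises(ValueError, match="crop"):
            augment(images[0], labels[0], TrainConfig(crop=64), seed=0)


class TestNormalize:
    def test_window_center_maps_to_half(self):
        img = np.full((8, 8), 35.0)
        assert np.all(normalize(img, level=35, width=80) == 0.5)

    def test_window_edges_map_to_zero_and_one(self):
        img = np.array([-5.0, 75.0])
        out = normalize(img, level=35, width=80)
        assert out[0] == 0.0 and out[1] == 1.0

    def test_output_range_on_synthetic_slice(self, tiny_slices):
        out = normalize(tiny_slices[0][0])
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            normalize(np.array([1.0, np.inf]))


class TestNetwork:
    def test_output_shape_matches_input(self):
        model = SegNet2D(SegModelSpec(in_channels=4, widths=(4, 8)), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 4, 16, 16)).astype(np.float32)
        logits = model.forward(x)
        assert logits.shape == (2, 10, 16, 16)

    def test_indivisible_spatial_shape_rejected(self):
        model = SegNet2D(SegModelSpec(in_channels=1, widths=(4, 8)))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 18, 18), dtype=np.float32))

    def test_conv_gradients_match_finite_differences(self):
        # the conv layer is smooth, so central differences are accurate even
        # in float32; pooling argmax flips make a full-network check unstable
        from pcscale.segtrain.nn import Conv3x3

        rng = np.random.default_rng(3)
        conv = Conv3x3(2, 3, rng)
        x = rng.normal(size=(1, 2, 6, 6)).astype(np.float32)
        target = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)

        def loss_at():
            return float(0.5 * ((conv.forward(x) - target) ** 2).sum())

        dy = conv.forward(x) - target
        dx = conv.backward(dy)
        eps = 1e-2
        for p, g in conv.params():
            flat, gflat = p.reshape(-1), g.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                down = loss_at()
                flat[idx] = orig
                assert (up - down) / (2 * eps) == pytest.approx(
                    gflat[idx], rel=1e-2, abs=1e-3
                )
        # input gradient via the same quadratic loss
        for idx in rng.choice(x.size, size=5, replace=False):
            flat = x.reshape(-1)
            orig = flat[idx]
            flat[idx] = orig + eps
            conv2 = conv.forward(x)
            up = float(0.5 * ((conv2 - target) ** 2).sum())
            flat[idx] = orig - eps
            down = float(0.5 * ((conv.forward(x) - target) ** 2).sum())
            flat[idx] = orig
            conv.forward(x)  # restore cached input
            assert (up - down) / (2 * eps) == pytest.approx(
                dx.reshape(-1)[idx], rel=1e-2, abs=1e-3
            )

    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(1, 3, 4, 4)).astype(np.float64)
        y = rng.integers(0, 3, (1, 4, 4))
        w = np.array([1.0, 2.0, 0.5])
        _, dlogits = softmax_cross_entropy(logits, y, w)
        eps = 1e-6
        for idx in rng.choice(logits.size, size=10, replace=False):
            flat = logits.reshape(-1)
            orig = flat[idx]
            flat[idx] = orig + eps
            up = softmax_cross_entropy(logits, y, w)[0]
            flat[idx] = orig - eps
            down = softmax_cross_entropy(logits, y, w)[0]
            flat[idx] = orig
            assert (up - down) / (2 * eps) == pytest.approx(
                dlogits.reshape(-1)[idx], rel=1e-4, abs=1e-10
            )

    def test_class_weights_median_frequency(self):
        labels = np.array([0] * 90 + [1] * 9 + [2] * 1)
        w = class_weights(labels, n_classes=4)
        assert w[3] == 0.0  # absent class
        assert w[0] < w[1] < w[2]
        assert w[1] == pytest.approx(1.0)  # median-frequency class


class TestTraining:
    def test_zero_epoch_budget_warns_untrained(self, tiny_slices):
        images, labels, z = tiny_slices
        cfg = TrainConfig(max_epochs=0, crop=48, scale_amplitude=0.0)
        with pytest.warns(UserWarning, match="untrained"):
            model, hist = train_segmenter(images, labels, cfg,
                                          tune_images=images, tune_labels=labels)
        assert len(hist) == 0

    def test_empty_tuning_set_rejected(self, tiny_slices):
        images, labels, _ = tiny_slices
        with pytest.raises(ValueError, match="tuning"):
            train_segmenter(images, labels, TrainConfig(crop=48))

    def test_lr_schedule_drops_are_exact_decade_steps(self, tiny_slices):
        images, labels, z = tiny_slices
        cfg = TrainConfig(max_epochs=25, crop=48, scale_amplitude=0.0, seed=0,
                          patience=2, min_delta=10.0)  # force plateaus
        _, hist = train_segmenter(images, labels, cfg,
                                  tune_images=images, tune_labels=labels,
                                  train_z=z, tune_z=z)
        lrs = hist.lr.to_numpy()
        assert np.all(np.diff(lrs) <= 1e-15)
        ratios = lrs[1:] / lrs[:-1]
        assert set(np.round(ratios, 6)) <= {1.0, 0.1}

    def test_overfit_learns_structures(self, tiny_slices):
        images, labels, z = tiny_slices
        cfg = TrainConfig(max_epochs=60, crop=48, scale_amplitude=0.0, seed=0)
        model, hist = train_segmenter(images, labels, cfg,
                                      tune_images=images, tune_labels=labels,
                                      train_z=z, tune_z=z)
        pred = predict_slices(model, images, cfg, z=z)
        # pixel accuracy is a coarse but fast signal that training works
        acc = (pred == labels).mean()
        assert acc >= 0.9
        assert hist.train_loss.iloc[-1] < hist.train_loss.iloc[0]

    def test_checkpoint_has_lowest_final_phase_tuning_loss(self, tiny_slices):
        from pcscale.segtrain.train import _tuning_loss

        images, labels, z = tiny_slices
        cfg = TrainConfig(max_epochs=20, crop=48, scale_amplitude=0.0, seed=1,
                          balance_fraction=0.5)
        model, hist = train_segmenter(images, labels, cfg,
                                      tune_images=images, tune_labels=labels,
                                      train_z=z, tune_z=z)
        final_phase = hist[hist.epoch > 10]
        restored = _tuning_loss(model, normalize(images), labels, z=z)
        assert restored <= final_phase.tune_loss.min() + 1e-9


class TestEvaluateFolds:
    def _cases(self, k=4):
        cases = []
        for i in range(k):
            images, labels, _ = phantom.synthetic_slices(n=4, size=48, seed=10 + i)
            cases.append((images, labels))
        return cases

    def test_oracle_predictor_scores_unit_iou(self):
        cases = self._cases(4)
        truth = {id(c[0]): c[1] for c in cases}

        def oracle(image_stack):
            return truth[id(image_stack)]

        # the oracle needs the original arrays: wrap to match by content
        def oracle_by_content(image_stack):
            for imgs, labs in cases:
                if np.array_equal(imgs, image_stack):
                    return labs
            raise AssertionError("unknown case")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate_folds(cases, k=2, seed=0, predictor=oracle_by_content)
        assert report.shape == (9, 3)
        assert np.allclose(report[["fold_1", "fold_2"]].to_numpy(), 1.0)

    def test_report_shape_range_and_mean_column(self):
        cases = self._cases(4)

        def half_oracle(image_stack):
            for imgs, labs in cases:
                if np.array_equal(imgs, image_stack):
                    out = labs.copy()
                    out[:, :, ::2] = 0  # degrade every other column
                    return out
            raise AssertionError

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate_folds(cases, k=2, seed=0, predictor=half_oracle)
        vals = report[["fold_1", "fold_2"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        np.testing.assert_allclose(
            report["mean"].to_numpy(), vals.mean(axis=1), atol=1e-12
        )

    def test_fewer_cases_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            evaluate_folds(self._cases(2), k=3)
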