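"""The compact fully-convolutional classifier: parameter accounting,
gradient correctness, training behavior, and dense-map semantics."""

import numpy as np
import pytest

from hfhisto.cnn import (
    REFERENCE_ARCHITECTURE,
    ArchitectureSpec,
    ProbabilityMap,
    StageSpec,
    TrainingConfig,
    build_model,
    count_parameters,
    image_probability,
    predict_probability_map,
    train,
)
from hfhisto.cnn import _softmax_xent, normalize_patches
from hfhisto.errors import (
    DegenerateInputError,
    InvalidArchitectureError,
    InvalidArgumentError,
    InvalidDataError,
)


class TestParameterCount:
    def test_single_conv_with_bn_closed_form(self):
        spec = ArchitectureSpec(stages=(StageSpec(3, 16),), input_px=64, head_kernel_px=1)
        # 3*3*3*16 = 432 conv weights + 2*16 BN scale/shift = 464, plus the 1x1 head
        head = 1 * 1 * 16 * 2 + 2
        assert spec.parameter_count() == 464 + head
        assert count_parameters(build_model(spec)) == spec.parameter_count()

    def test_model_with_no_layers_counts_zero(self):
        m = build_model(REFERENCE_ARCHITECTURE)
        m.layers = []
        assert count_parameters(m) == 0

    def test_reference_layout_in_published_band(self):
        n = count_parameters(build_model(REFERENCE_ARCHITECTURE))
        assert n == REFERENCE_ARCHITECTURE.parameter_count() == 13_306
        assert 12_800 <= n <= 14_200

    def test_collapsing_architecture_rejected(self):
        bad = ArchitectureSpec(stages=(StageSpec(3, 8, pool=True),) * 6)
        with pytest.raises(InvalidArchitectureError):
            build_model(bad)


class TestGradients:
    def test_backprop_matches_finite_differences_on_smooth_net(self, rng):
        # conv + BN only (no ReLU/pool kinks): gradients must match closely
        spec = ArchitectureSpec(
            stages=(StageSpec(3, 4, activation=False), StageSpec(3, 5, activation=False)),
            input_px=8, head_kernel_px=4,
        )
        model = build_model(spec, rng_seed=1)
        x = rng.normal(size=(5, 8, 8, 3)).astype(np.float32)
        y = rng.integers(0, 2, 5)

        def loss():
            return _softmax_xent(model.forward(x, train=True).reshape(5, -1), y)

        _, d, _ = loss()
        model.backward(d.reshape(5, 1, 1, 2).copy())
        grads = {n: g.copy() for n, _, g in model.parameters()}
        errs = []
        for name, arr, _ in model.parameters():
            flat = arr.ravel()
            for j in rng.choice(flat.size, min(6, flat.size), replace=False):
                eps, old = 1e-2, flat[j]
                flat[j] = old + eps
                l1, *_ = loss()
                flat[j] = old - eps
                l2, *_ = loss()
                flat[j] = old
                num = (l1 - l2) / (2 * eps)
                ana = grads[name].ravel()[j]
                errs.append(abs(num - ana) / max(1e-3, abs(num) + abs(ana)))
        assert max(errs) < 1e-2

    def test_single_minibatch_overfit_loss_non_increasing(self, rng):
        x = rng.integers(0, 255, (32, 64, 64, 3), dtype=np.uint8)
        y = rng.integers(0, 2, 32)
        model = build_model(rng_seed=0)
        _, log = train(model, (x, y), None,
                       TrainingConfig(epochs=25, batch_size=32, learning_rate=0.01, rng_seed=0))
        losses = [e["train_loss"] for e in log]
        best_so_far = np.minimum.accumulate(losses)
        assert (np.diff(best_so_far) <= 1e-12).all() and losses[-1] < losses[0]


class TestTraining:
    def test_separable_fixture_reaches_perfect_accuracy(self):
        x = np.concatenate([np.full((100, 64, 64, 3), 40, np.uint8),
                            np.full((100, 64, 64, 3), 200, np.uint8)])
        y = np.array([0] * 100 + [1] * 100)
        model = build_model(rng_seed=0)
        _, log = train(model, (x, y), None, TrainingConfig(epochs=10, rng_seed=0))
        assert max(e["train_acc"] for e in log) == 1.0

    def test_default_config_runs_30_epochs_at_batch_64(self):
        cfg = TrainingConfig()
        assert cfg.epochs == 30 and cfg.batch_size == 64 and cfg.optimizer == "sgd"

    def test_single_class_training_set_rejected(self, rng):
        x = rng.integers(0, 255, (8, 64, 64, 3), dtype=np.uint8)
        with pytest.raises(InvalidDataError):
            train(build_model(), (x, np.zeros(8, int)), None, TrainingConfig(epochs=1))

    def test_wrong_patch_size_rejected(self, rng):
        x = rng.integers(0, 255, (8, 32, 32, 3), dtype=np.uint8)
        y = np.array([0, 1] * 4)
        with pytest.raises(InvalidArgumentError):
            train(build_model(), (x, y), None, TrainingConfig(epochs=1))

    def test_identical_seeds_give_identical_loss_sequences(self, rng):
        x = rng.integers(0, 255, (64, 64, 64, 3), dtype=np.uint8)
        y = np.array([0, 1] * 32)
        logs = []
        for _ in range(2):
            m = build_model(rng_seed=3)
            _, log = train(m, (x, y), None, TrainingConfig(epochs=2, rng_seed=3))
            logs.append([e["train_loss"] for e in log])
        assert logs[0] == logs[1]

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_model(rng_seed=5)
        b = build_model(rng_seed=5)
        for (na, wa, _), (nb, wb, _) in zip(a.parameters(), b.parameters()):
            assert na == nb and np.array_equal(wa, wb)

    def test_best_validation_epoch_weights_are_retained(self, rng):
        x = np.concatenate([np.full((40, 64, 64, 3), 40, np.uint8),
                            np.full((40, 64, 64, 3), 200, np.uint8)])
        y = np.array([0] * 40 + [1] * 40)
        m = build_model(rng_seed=0)
        m, log = train(m, (x, y), (x, y), TrainingConfig(epochs=4, rng_seed=0))
        best = max(e["val_acc"] for e in log)
        _, acc = __import__("hfhisto.cnn", fromlist=["x"])._evaluate_patches(
            m, normalize_patches(x), y)
        assert acc == best


class TestProbabilityMaps:
    def test_minimal_input_yields_one_by_one_map(self, rng):
        model = build_model(rng_seed=0)
        patch = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        pm = predict_probability_map(model, patch)
        assert pm.values.shape == (1, 1)

    def test_fully_convolutional_map_equals_sliding_window_crops(self, rng):
        model = build_model(rng_seed=1)
        roi = rng.integers(0, 255, (320, 320, 3), dtype=np.uint8)
        pm = predict_probability_map(model, roi)
        stride = model.spec.downsample_factor
        for r, c in rng.integers(0, pm.values.shape[0], size=(10, 2)):
            crop = roi[stride * r : stride * r + 64, stride * c : stride * c + 64]
            solo = predict_probability_map(model, crop).values[0, 0]
            assert abs(solo - pm.values[r, c]) < 1e-5

    def test_map_values_are_probabilities(self, rng):
        model = build_model(rng_seed=2)
        roi = rng.integers(0, 255, (256, 256, 3), dtype=np.uint8)
        pm = predict_probability_map(model, roi)
        assert (pm.values >= 0).all() and (pm.values <= 1).all()

    def test_roi_below_receptive_field_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            predict_probability_map(build_model(), rng.integers(0, 255, (32, 32, 3), dtype=np.uint8))

    def test_image_probability_is_the_map_mean(self, rng):
        assert image_probability(ProbabilityMap(np.full((4, 4), 0.7), 8)) == pytest.approx(0.7)
        half = np.zeros((2, 4)); half[:, 2:] = 1.0
        assert image_probability(ProbabilityMap(half, 8)) == 0.5
        vals = rng.random((7, 9)).astype(np.float32)
        p = image_probability(ProbabilityMap(vals, 8))
        assert vals.min() <= p <= vals.max()
        with pytest.raises(DegenerateInputError):
            image_probability(ProbabilityMap(np.zeros((0, 0)), 8))


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, rng, tmp_path):
        model = build_model(rng_seed=4)
        roi = rng.integers(0, 255, (128, 128, 3), dtype=np.uint8)
        before = predict_probability_map(model, roi).values
        path = tmp_path / "ckpt.npz"
        model.save(path)
        from hfhisto.cnn import FullyConvNet

        loaded = FullyConvNet.load(path)
        after = predict_probability_map(loaded, roi).values
        assert np.array_equal(before, after)

    def test_probability_map_tiff_roundtrip(self, rng, tmp_path):
        import tifffile

        from hfhisto.cnn import export_map_tiff

        pm = ProbabilityMap(rng.random((9, 9)).astype(np.float32), 8)
        export_map_tiff(pm, tmp_path / "map.tif")
        back = tifffile.imread(tmp_path / "map.tif")
        assert back.dtype == np.float32 and np.array_equal(back, pm.values)
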