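"""Architecture identity, shape propagation vs an independent oracle,
leave-one-speed-out combinatorics, and training behaviour of the regressor."""

import numpy as np
import pytest

from sonomoment import moment_net as mn
from sonomoment import synthetic_data as sd


def shape_oracle(hw, filters=(8, 16, 32, 32, 32, 32, 32), pool=2, stride=2):
    """Standalone shape propagation: 'same' convs keep size, each pooling
    maps n -> floor((n - pool)/stride) + 1; returns the flattened FC input."""
    h, w = hw
    for i, f in enumerate(filters, start=1):
        if i < len(filters):
            h = (h - pool) // stride + 1
            w = (w - pool) // stride + 1
    return h * w * filters[-1], (h, w)


class TestArchitecture:
    @pytest.mark.parametrize("hw", [(100, 100), (200, 200), (300, 300)])
    def test_exactly_31_layers_with_6_poolings(self, hw):
        spec = mn.build_cnn(hw)
        kinds = [k for _, k in spec.layers]
        assert spec.n_layers == 31
        assert kinds.count("avgpool") == 6
        assert kinds.count("conv") == kinds.count("batchnorm") == kinds.count("relu") == 7
        assert kinds[-3:] == ["dropout", "fc", "regression"]

    def test_layer_list_independent_of_input_size(self):
        a = [n for n, _ in mn.build_cnn((100, 100)).layers]
        b = [n for n, _ in mn.build_cnn((300, 300)).layers]
        assert a == b

    def test_filter_counts_follow_design(self):
        assert mn.build_cnn((100, 100)).filters == (8, 16, 32, 32, 32, 32, 32)

    @pytest.mark.parametrize(
        "hw,fc_expected", [((100, 100), 32), ((200, 200), 288), ((300, 300), 512)]
    )
    def test_shape_propagation_matches_oracle(self, hw, fc_expected):
        spec = mn.build_cnn(hw)
        fc_oracle, last_hw = shape_oracle(hw)
        assert spec.fc_inputs == fc_oracle == fc_expected
        shapes = dict(mn.layer_output_shapes(spec))
        assert shapes["avgpool_6"][:2] == last_hw

    def test_300px_spatial_track(self):
        shapes = mn.layer_output_shapes(mn.build_cnn((300, 300)))
        pools = [s for n, s in shapes if n.startswith("avgpool")]
        assert [p[0] for p in pools] == [150, 75, 37, 18, 9, 4]

    def test_too_small_input_names_degenerate_layer(self):
        with pytest.raises(ValueError, match="avgpool"):
            mn.build_cnn((16, 16))

    def test_minimum_side_is_64(self):
        mn.build_cnn((64, 64))
        with pytest.raises(ValueError):
            mn.build_cnn((63, 63))


class TestMakeSplits:
    def _cycles(self, speeds=(0.5, 0.75, 1.0, 1.25, 1.5), n=8):
        return {s: list(range(n)) for s in speeds}

    def test_five_speeds_give_five_folds(self):
        assert len(mn.make_splits(self._cycles())) == 5

    def test_fold_sizes_20_5_15(self):
        split = mn.make_splits(self._cycles())
        for fold in split.folds:
            assert len(fold.train) == 20
            assert len(fold.validation) == 5
            assert len(fold.prediction) == 15

    def test_train_validation_fraction_62_5_pct(self):
        split = mn.make_splits(self._cycles())
        fold = split.folds[0]
        total = 5 * 8
        fit = len(fold.train) + len(fold.validation)
        assert fit / total == pytest.approx(0.625)
        assert len(fold.prediction) / total == pytest.approx(0.375)

    def test_validation_is_held_out_speed_fit_cycles(self):
        split = mn.make_splits(self._cycles())
        fold = split.fold_for(1.0)
        assert all(s == 1.0 for s, _ in fold.validation)
        assert all(s != 1.0 for s, _ in fold.train)

    def test_no_overlap_invariants(self):
        for fold in mn.make_splits(self._cycles()).folds:
            assert not (set(fold.train) & set(fold.validation))
            assert not ((set(fold.train) | set(fold.validation)) & set(fold.prediction))

    def test_missing_speed_rejected(self):
        cycles = self._cycles()
        cycles[1.5] = list(range(3))
        with pytest.raises(ValueError, match="1.5"):
            mn.make_splits(cycles)


@pytest.fixture(scope="module")
def tiny_fold(request):
    """A learnable 64x64 fold: ~260 training frames from 2 speeds."""
    cfg = sd.SyntheticConfig(
        speeds=(0.50, 1.00, 1.50),
        cycles_per_speed=2,
        fs_analog=40.0,
        fps_us=40.0,
        image_height_px=64,
        image_width_px=64,
        seed=21,
    )
    ds = sd.gen_walking_dataset(cfg)
    split = mn.make_splits(ds.cycles, cycles_per_speed=2, fit_cycles=1)
    fold = split.fold_for(1.00)
    train = mn.fold_frame_source(ds.cycles[s][k] for s, k in fold.train)
    val = mn.fold_frame_source(ds.cycles[s][k] for s, k in fold.validation)
    return train, val


class TestTraining:
    def test_loss_decreases_over_epochs(self, tiny_fold):
        train, _ = tiny_fold
        spec = mn.build_cnn((64, 64))
        cfg = mn.TrainConfig(mini_batch=32, max_epochs=4, seed=5)
        model = mn.train(spec, train, train.labels, cfg)
        losses = np.array(model.record["train_loss"])
        per_epoch = losses.reshape(4, -1).mean(axis=1)
        assert per_epoch[-1] < per_epoch[0]
        assert model.record["train_rmse"][-1] < model.record["train_rmse"][0]

    def test_constant_labels_converge_to_constant(self, tiny_fold):
        train, val = tiny_fold
        spec = mn.build_cnn((64, 64))
        c = 50.0
        # small fold, so a larger step and more passes than the walking runs
        cfg = mn.TrainConfig(
            mini_batch=16, max_epochs=20, lr_initial=0.01, lr_late=0.01, seed=5
        )
        model = mn.train(spec, train, np.full(len(train), c), cfg)
        pred = mn.predict(model, val)
        rmse = np.sqrt(np.mean((pred - c) ** 2))
        assert rmse < 0.05 * abs(c)

    def test_same_seed_identical_weights(self, tiny_fold):
        train, _ = tiny_fold
        spec = mn.build_cnn((64, 64))
        cfg = mn.TrainConfig(mini_batch=32, max_epochs=1, seed=9)
        m1 = mn.train(spec, train, train.labels, cfg)
        m2 = mn.train(spec, train, train.labels, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        assert m1.record["train_loss"] == m2.record["train_loss"]

    def test_validation_recorded_at_schedule(self, tiny_fold):
        train, val = tiny_fold
        spec = mn.build_cnn((64, 64))
        cfg = mn.TrainConfig(mini_batch=32, max_epochs=2, seed=5)
        model = mn.train(spec, train, train.labels, cfg, val, val.labels)
        val_every = max(len(train) // cfg.mini_batch, 1)
        its = [v["iteration"] for v in model.record["validation"]]
        assert its and all(i % val_every == 0 for i in its)

    def test_shape_mismatch_rejected(self, tiny_fold, rng):
        train, _ = tiny_fold
        spec = mn.build_cnn((100, 100))
        with pytest.raises(ValueError, match="does not match"):
            mn.train(spec, train, train.labels, mn.TrainConfig(max_epochs=1))

    def test_nonfinite_labels_rejected(self, tiny_fold):
        train, _ = tiny_fold
        labels = train.labels
        labels[0] = np.nan
        spec = mn.build_cnn((64, 64))
        with pytest.raises(ValueError, match="finite"):
            mn.train(spec, train, labels, mn.TrainConfig(max_epochs=1))

    def test_mean_image_from_training_set_only(self, tiny_fold):
        train, _ = tiny_fold
        spec = mn.build_cnn((64, 64))
        cfg = mn.TrainConfig(mini_batch=32, max_epochs=1, seed=5)
        model = mn.train(spec, train, train.labels, cfg)
        expected = np.mean(
            [np.asarray(train[i], dtype=np.float64) for i in range(len(train))],
            axis=0,
        )
        np.testing.assert_allclose(model.mean_image, expected, atol=1e-5)


@pytest.fixture(scope="module")
def trained(tiny_fold):
    train, val = tiny_fold
    spec = mn.build_cnn((64, 64))
    cfg = mn.TrainConfig(mini_batch=32, max_epochs=2, seed=5)
    return mn.train(spec, train, train.labels, cfg), val


class TestPredict:
    def test_one_prediction_per_frame(self, trained):
        model, val = trained
        assert mn.predict(model, val).shape == (len(val),)

    def test_identical_frames_identical_predictions(self, trained, rng):
        model, _ = trained
        frame = rng.random((64, 64)).astype(np.float32)
        preds = mn.predict(model, np.stack([frame] * 5))
        assert np.ptp(preds) == 0.0

    def test_shape_mismatch_rejected(self, trained, rng):
        model, _ = trained
        with pytest.raises(ValueError, match="does not match"):
            mn.predict(model, rng.random((3, 32, 32)))

    def test_checkpoint_roundtrip_preserves_predictions(self, trained, tmp_path):
        model, val = trained
        path = tmp_path / "fold.ckpt.npz"
        model.save(path)
        loaded = mn.TrainedModel.load(path)
        np.testing.assert_array_equal(mn.predict(model, val), mn.predict(loaded, val))
        assert loaded.spec == model.spec
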