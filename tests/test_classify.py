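import copy

import numpy as np
import pytest

from myogrip.classify import (
    LabeledDataset,
    TrainingConfig,
    build_model,
    forward,
    forward_batch,
    load_model,
    predict_batch,
    random_search,
    save_model,
    stratified_split,
    train,
)


def oracle_forward(model, x):
    """Plain-arithmetic forward pass: explicit loops, no numpy linear algebra."""
    a = list(x)
    n_dense = len(model.weights)
    for layer in range(n_dense):
        W, b = model.weights[layer], model.biases[layer]
        z = []
        for j in range(W.shape[1]):
            s = b[j]
            for i in range(W.shape[0]):
                s += a[i] * W[i, j]
            z.append(s)
        if layer < n_dense - 1:
            a = [max(v, 0.0) for v in z]
        elif model.output_activation == "softmax":
            m = max(z)
            e = [np.exp(v - m) for v in z]
            tot = sum(e)
            a = [v / tot for v in e]
        else:
            a = [1.0 / (1.0 + np.exp(-z[0]))]
    return np.array(a)


def separable_dataset(seed=0, n=40, d=6, classes=(1, 2)):
    """Gaussian blobs far apart: linearly separable by construction."""
    rng = np.random.default_rng(seed)
    per = n // len(classes)
    X, y = [], []
    for i, cls in enumerate(classes):
        center = np.zeros(d)
        center[i % d] = 5.0
        X.append(rng.standard_normal((per, d)) * 0.3 + center)
        y.extend([cls] * per)
    return LabeledDataset(np.vstack(X), np.array(y))


class TestBuildModel:
    def test_default_multiclass_has_five_layers(self):
        model = build_model(12, [1, 2, 3])
        assert model.n_layers == 5
        kinds = [k for k, _ in model.layer_spec]
        assert kinds == ["dense", "dropout", "dense", "dropout", "dense"]
        assert model.layer_spec[-1] == ("dense", 3)
        assert model.output_activation == "softmax"
        assert model.dropout_rates() == [0.2, 0.2]

    def test_binary_variant_sigmoid_width_one(self):
        model = build_model(12, [1, 3], binary=True)
        assert model.layer_spec[-1] == ("dense", 1)
        assert model.output_activation == "sigmoid"

    def test_equal_seeds_identical_weights(self):
        a = build_model(12, [1, 2, 3], seed=4)
        b = build_model(12, [1, 2, 3], seed=4)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seeds_differ(self):
        a = build_model(12, [1, 2, 3], seed=4)
        b = build_model(12, [1, 2, 3], seed=5)
        assert not np.array_equal(a.weights[0], b.weights[0])

    def test_fan_in_init_bounds(self):
        model = build_model(16, [1, 2, 3], seed=0)
        for w in model.weights:
            limit = 1.0 / np.sqrt(w.shape[0])
            assert np.all(np.abs(w) <= limit)

    @pytest.mark.parametrize("kwargs", [
        {"n_inputs": 0}, {"hidden_widths": (0, 16)}, {"dropout_rate": 0.0},
        {"dropout_rate": 1.0},
    ])
    def test_invalid_builds_rejected(self, kwargs):
        base = {"n_inputs": 12, "classes": [1, 2, 3]}
        with pytest.raises(ValueError):
            build_model(**{**base, **kwargs})

    def test_binary_requires_two_classes(self):
        with pytest.raises(ValueError):
            build_model(12, [1, 2, 3], binary=True)


class TestForward:
    def test_zero_weights_give_uniform_probabilities(self):
        model = build_model(12, [1, 2, 3], seed=0)
        for w in model.weights:
            w[:] = 0.0
        pred = forward(model, np.zeros(12))
        np.testing.assert_allclose(pred.probabilities, np.full(3, 1 / 3))
        assert pred.class_id == 1  # lowest index on exact ties

    def test_probabilities_sum_to_one(self, rng):
        model = build_model(12, [1, 2, 3], seed=1)
        for _ in range(20):
            pred = forward(model, rng.standard_normal(12))
            assert abs(pred.probabilities.sum() - 1.0) < 1e-9
            assert pred.confidence == pytest.approx(pred.probabilities.max())

    def test_hand_built_two_layer_model(self):
        # dense(2) -> dense(2, softmax) on a fixed vector, checked against
        # hand matrix arithmetic
        model = build_model(2, [1, 2], hidden_widths=(2, 2), seed=0)
        model.layer_spec = [("dense", 2), ("dense", 2)]
        W0 = np.array([[1.0, 0.0], [0.0, -1.0]])
        W1 = np.array([[2.0, -1.0], [0.5, 1.0]])
        model.weights = [W0, W1]
        model.biases = [np.array([0.5, 0.0]), np.array([0.0, 1.0])]
        x = np.array([1.0, 2.0])
        # h = relu([1*1+0.5, -2]) = [1.5, 0]; z = h @ W1 + b1 = [3.0, -1.5+1]
        z = np.array([3.0, -0.5])
        expected = np.exp(z) / np.exp(z).sum()
        pred = forward(model, x)
        np.testing.assert_allclose(pred.probabilities, expected, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        model = build_model(12, [1, 2, 3], seed=0)
        with pytest.raises(ValueError):
            forward(model, np.zeros(7))

    def test_matches_plain_arithmetic_oracle(self, rng):
        for trial in range(30):
            n_in = int(rng.integers(2, 8))
            model = build_model(n_in, [1, 2, 3], hidden_widths=(5, 4), seed=trial)
            x = rng.standard_normal(n_in)
            pred = forward(model, x)
            np.testing.assert_allclose(pred.probabilities, oracle_forward(model, x),
                                       rtol=1e-9, atol=1e-12)

    def test_sigmoid_oracle(self, rng):
        for trial in range(10):
            model = build_model(4, [1, 3], hidden_widths=(5, 4), binary=True, seed=trial)
            x = rng.standard_normal(4)
            p = oracle_forward(model, x)[0]
            pred = forward(model, x)
            np.testing.assert_allclose(pred.probabilities, [1 - p, p], rtol=1e-9)
            assert pred.class_id == (3 if p > 0.5 else 1)

    def test_argmax_consistency_random_models(self, rng):
        for trial in range(20):
            model = build_model(6, [1, 2, 3], seed=100 + trial)
            x = rng.standard_normal(6)
            pred = forward(model, x)
            assert pred.class_id == model.classes[int(np.argmax(pred.probabilities))]


class TestTrain:
    def test_separable_data_reaches_full_accuracy(self):
        data = separable_dataset()
        model = build_model(6, data.classes, seed=0)
        history = train(model, data, TrainingConfig(seed=0))
        assert history.accuracy[-1] == 1.0

    def test_history_lengths_match_epochs(self):
        data = separable_dataset()
        model = build_model(6, data.classes, seed=0)
        history = train(model, data, TrainingConfig(epochs=5, seed=0))
        assert len(history.loss) == 5
        assert len(history.accuracy) == 5
        assert len(history.val_loss) == 5

    def test_same_seed_identical_final_weights(self):
        data = separable_dataset()
        m1 = build_model(6, data.classes, seed=3)
        m2 = build_model(6, data.classes, seed=3)
        cfg = TrainingConfig(epochs=20, seed=3)
        train(m1, data, cfg)
        train(m2, data, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        data = separable_dataset()
        model = build_model(6, data.classes, seed=0)
        before = copy.deepcopy(model.weights)
        train(model, data, TrainingConfig(learning_rate=0.0, epochs=3, seed=0))
        for w0, w1 in zip(before, model.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_missing_class_in_training_split_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 4))
        y = np.array([1] * 10)
        data = LabeledDataset(X, y, classes=[1, 2])
        model = build_model(4, [1, 2], seed=0)
        with pytest.raises(ValueError, match="class 2"):
            train(model, data, TrainingConfig(seed=0), presplit=True)

    def test_binary_training_on_sigmoid_head(self):
        data = separable_dataset(classes=(1, 3))
        model = build_model(6, data.classes, binary=True, seed=0)
        history = train(model, data, TrainingConfig(loss="binary", epochs=100, seed=0))
        assert history.accuracy[-1] == 1.0

    def test_small_step_loss_nonincreasing(self):
        # lr -> 0 regime: allow <= 5% violating epochs from mini-batch noise
        data = separable_dataset(seed=1, n=60)
        model = build_model(6, data.classes, seed=1)
        history = train(
            model, data,
            TrainingConfig(learning_rate=1e-4, epochs=100, seed=1, splits=(1.0, 0.0, 0.0)),
            presplit=True,
        )
        diffs = np.diff(history.loss)
        assert np.mean(diffs > 0) <= 0.05

    def test_dropout_inactive_at_inference(self, rng):
        model = build_model(6, [1, 2, 3], seed=0)
        x = rng.standard_normal((4, 6))
        out1, _ = forward_batch(model, x)
        out2, _ = forward_batch(model, x)
        np.testing.assert_array_equal(out1, out2)


class TestStratifiedSplit:
    def test_fraction_sizes(self):
        y = np.array([1] * 10 + [2] * 10)
        tr, va, te = stratified_split(y, (0.6, 0.2, 0.2), seed=0)
        assert len(tr) == 12 and len(va) == 4 and len(te) == 4
        assert sorted(np.concatenate([tr, va, te])) == list(range(20))

    def test_stratification(self):
        y = np.array([1] * 10 + [2] * 10)
        tr, _, _ = stratified_split(y, (0.6, 0.2, 0.2), seed=0)
        assert (y[tr] == 1).sum() == 6


class TestRandomSearch:
    def test_single_draw_is_best(self):
        data = separable_dataset()
        best, trials = random_search(data, n_draws=1, epoch_grid=(20,), seed=0)
        assert len(trials) == 1
        assert best.epochs == 20
        assert best.learning_rate == pytest.approx(trials[0]["learning_rate"])

    def test_tie_broken_by_trial_order(self):
        data = separable_dataset()
        best, trials = random_search(data, n_draws=3, epoch_grid=(20,), seed=0)
        accs = [t["val_accuracy"] for t in trials]
        first_best = int(np.argmax(accs))  # argmax returns first on ties
        assert best.learning_rate == pytest.approx(trials[first_best]["learning_rate"])

    def test_draws_within_declared_ranges(self):
        data = separable_dataset()
        _, trials = random_search(data, n_draws=5, lr_range=(1e-4, 1e-2),
                                  epoch_grid=(10, 20), seed=1)
        for t in trials:
            assert 1e-4 <= t["learning_rate"] <= 1e-2
            assert t["epochs"] in (10, 20)

    def test_search_dominates_default_run(self):
        # best validation accuracy >= any single default-config run, over 5 seeds
        for seed in range(5):
            data = separable_dataset(seed=seed)
            best, trials = random_search(data, n_draws=3, epoch_grid=(30,), seed=seed)
            model = build_model(6, data.classes, seed=seed)
            history = train(model, data, TrainingConfig(epochs=30, seed=seed))
            best_acc = max(t["val_accuracy"] for t in trials)
            assert best_acc >= history.val_accuracy[-1]

    def test_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            random_search(separable_dataset(), n_draws=0, seed=0)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        model = build_model(12, [1, 2, 3], seed=7)
        path = save_model(model, tmp_path / "model.json")
        back = load_model(path)
        assert back.layer_spec == model.layer_spec
        assert back.classes == model.classes
        for w1, w2 in zip(model.weights, back.weights):
            np.testing.assert_array_equal(w1, w2)
        x = rng.standard_normal(12)
        np.testing.assert_array_equal(forward(model, x).probabilities,
                                      forward(back, x).probabilities)

    def test_unknown_format_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"format": "other"}')
        with pytest.raises(ValueError):
            load_model(bad)


class TestLabeledDataset:
    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError):
            LabeledDataset(np.zeros((3, 2)), np.array([1, 2, 9]), classes=[1, 2])

    def test_from_feature_vectors_requires_labels(self, rng):
        from myogrip.features import FeatureVector

        fv = FeatureVector(values=rng.uniform(size=4), layout="rms", n_channels=2,
                           n_per_channel=2, label=None)
        with pytest.raises(ValueError):
            LabeledDataset.from_feature_vectors([fv])
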