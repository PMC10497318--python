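"""Backpropagation network: gradients, training, evaluation invariants."""

import numpy as np
import pandas as pd
import pytest

from emgdry.errors import ConfigurationError, FeatureMismatchError
from emgdry.features import FeatureDataset
from emgdry.network import (
    NetworkModel,
    TrainConfig,
    cross_evaluate,
    evaluate,
    forward,
    init_network,
    load_model,
    loss_and_gradients,
    save_model,
    train,
)
from emgdry.protocol import CLASS_ORDER


def gaussian_cluster_dataset(
    n_per_class=120, n_features=12, separation=10.0, seed=0, labels=CLASS_ORDER
):
    """Well-separated unit-variance Gaussian clusters, one per class."""
    rng = np.random.default_rng(seed)
    centroids = np.zeros((len(labels), n_features))
    for i in range(len(labels)):
        centroids[i, i % n_features] = separation
    rows, y = [], []
    for i, lab in enumerate(labels):
        rows.append(centroids[i] + rng.standard_normal((n_per_class, n_features)))
        y += [lab] * n_per_class
    X = np.vstack(rows)
    features = ("RMS", "MAV", "VAR")[: n_features // 4]
    cols = [f"{f}_ch{c}" for f in features for c in range(1, 5)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = y
    return FeatureDataset(df=df, feature_names=features, channels=(1, 2, 3, 4))


def onehot(idx, k=5):
    out = np.zeros((len(idx), k))
    out[np.arange(len(idx)), idx] = 1.0
    return out


class TestInit:
    def test_shapes_for_topology(self):
        m = init_network(12, seed=0)
        assert [w.shape for w in m.weights] == [(12, 20), (20, 8), (8, 5)]
        assert [b.shape for b in m.biases] == [(20,), (8,), (5,)]

    def test_deterministic(self):
        a, b = init_network(8, seed=5), init_network(8, seed=5)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    @pytest.mark.parametrize("n_in", [3, 21])
    def test_input_range_enforced(self, n_in):
        with pytest.raises(ConfigurationError):
            init_network(n_in)


class TestForward:
    def test_zero_parameters_give_uniform_probabilities(self):
        m = init_network(6, seed=0)
        m.weights = [np.zeros_like(w) for w in m.weights]
        m.biases = [np.zeros_like(b) for b in m.biases]
        probs = forward(m, np.ones(6))
        assert np.allclose(probs, 0.2)

    def test_probabilities_sum_to_one(self):
        m = init_network(10, seed=1)
        X = np.random.default_rng(0).standard_normal((40, 10))
        probs = forward(m, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_output_bias_monotonicity(self):
        m = init_network(10, seed=1)
        x = np.random.default_rng(2).standard_normal(10)
        before = forward(m, x)[0, 3]
        m.biases[-1][3] += 10.0
        after = forward(m, x)[0, 3]
        assert after > before

    def test_dimension_mismatch_rejected(self):
        m = init_network(10, seed=1)
        with pytest.raises(FeatureMismatchError):
            forward(m, np.ones(7))


def numeric_gradients(model, X, Y, h=1e-6):
    def loss():
        return loss_and_gradients(model, X, Y)[0]

    grads = []
    for W in model.weights + model.biases:
        g = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + h
            lp = loss()
            W[idx] = orig - h
            lm = loss()
            W[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        grads.append(g)
    return grads


@pytest.mark.parametrize("activation", ["tanh", "sigmoid"])
def test_backprop_matches_finite_differences(activation):
    rng = np.random.default_rng(11)
    m = init_network(6, seed=3, hidden_activation=activation)
    X = rng.standard_normal((5, 6))
    Y = onehot(rng.integers(0, 5, size=5))
    _, gw, gb = loss_and_gradients(m, X, Y)
    numeric = numeric_gradients(m, X, Y)
    for analytic, num in zip(gw + gb, numeric):
        err = np.linalg.norm(analytic - num) / max(np.linalg.norm(num), 1e-8)
        assert err < 1e-5


class TestTrain:
    def test_vanishing_learning_rate_freezes_parameters(self):
        ds = gaussian_cluster_dataset(n_per_class=20, seed=1)
        m = init_network(12, seed=0)
        w0 = [w.copy() for w in m.weights]
        train(m, ds, TrainConfig(learning_rate=1e-12, batch_size=32,
                                 max_epochs=3, seed=0))
        for w, orig in zip(m.weights, w0):
            assert np.allclose(w, orig, atol=1e-9)

    def test_separable_clusters_learned(self):
        """Held-out accuracy >= 0.95 on 10-sigma-separated clusters; a
        nearest-centroid oracle confirms the problem is trivially separable."""
        ds = gaussian_cluster_dataset(n_per_class=120, seed=2)
        rng = np.random.default_rng(0)
        mask = rng.random(ds.n) < 0.8
        train_ds, test_ds = ds.subset_rows(mask), ds.subset_rows(~mask)
        m = init_network(12, seed=4)
        m, history = train(
            m, train_ds, TrainConfig(learning_rate=0.05, batch_size=128,
                                     max_epochs=80, seed=4)
        )
        rep = evaluate(m, test_ds, provenance=("x", "x"))
        assert rep.accuracy >= 0.95

        # independent oracle: class-mean centroids on the training rows
        Xtr, ytr = train_ds.matrix, train_ds.labels
        cents = {lab: Xtr[ytr == lab].mean(axis=0) for lab in CLASS_ORDER}
        Xte, yte = test_ds.matrix, test_ds.labels
        pred = [
            min(cents, key=lambda lab: np.linalg.norm(x - cents[lab])) for x in Xte
        ]
        assert np.mean(np.asarray(pred) == yte) >= 0.99

    def test_full_batch_small_lr_loss_monotone(self):
        ds = gaussian_cluster_dataset(n_per_class=40, seed=3)
        m = init_network(12, seed=1)
        _, history = train(
            m, ds, TrainConfig(learning_rate=1e-4, batch_size=ds.n,
                               max_epochs=30, seed=1)
        )
        losses = np.array(history["train_loss"])
        assert np.all(np.diff(losses) <= 1e-10)

    def test_single_class_warns(self):
        ds = gaussian_cluster_dataset(n_per_class=30, seed=5)
        only = ds.subset_rows(ds.df["label"] == "fist")
        m = init_network(12, seed=0)
        with pytest.warns(UserWarning):
            train(m, only, TrainConfig(learning_rate=0.01, batch_size=8,
                                       max_epochs=2, seed=0))

    def test_feature_count_mismatch_rejected(self):
        ds = gaussian_cluster_dataset(n_per_class=10, seed=0)
        m = init_network(8, seed=0)
        with pytest.raises(FeatureMismatchError):
            train(m, ds, TrainConfig(max_epochs=1))


def trained_toy_model(seed=0):
    ds = gaussian_cluster_dataset(n_per_class=60, seed=seed)
    m = init_network(12, seed=seed)
    m, _ = train(m, ds, TrainConfig(learning_rate=0.05, batch_size=64,
                                    max_epochs=150, seed=seed))
    return m, ds


class TestEvaluate:
    def test_perfect_predictions_give_diagonal_confusion(self):
        # label the rows with the model's own argmax decisions
        m, ds = trained_toy_model()
        probs = forward(m, (ds.matrix - m.norm_mean) / m.norm_scale)
        relabelled = ds.df.copy()
        relabelled["label"] = [m.class_labels[i] for i in probs.argmax(axis=1)]
        rep = evaluate(
            m,
            FeatureDataset(relabelled, ds.feature_names, ds.channels),
            provenance=("a", "a"),
        )
        assert rep.accuracy == 1.0
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))
        support = rep.confusion.sum(axis=1) > 0
        assert np.allclose(rep.per_class_recall[support], 1.0)

    def test_confusion_row_sums_equal_class_counts(self):
        m, ds = trained_toy_model(seed=1)
        rep = evaluate(m, ds, provenance=("a", "a"))
        counts = ds.df["label"].value_counts()
        for i, lab in enumerate(rep.class_labels):
            assert rep.confusion[i].sum() == counts.get(lab, 0)
        assert rep.confusion.sum() == rep.n == ds.n

    def test_random_labels_give_chance_accuracy(self):
        m, ds = trained_toy_model(seed=2)
        rng = np.random.default_rng(9)
        shuffled = ds.df.copy()
        shuffled["label"] = rng.choice(CLASS_ORDER, size=ds.n)
        rep = evaluate(
            m,
            FeatureDataset(shuffled, ds.feature_names, ds.channels),
            provenance=("a", "a"),
        )
        assert rep.accuracy == pytest.approx(0.2, abs=0.07)

    def test_empty_test_set_rejected(self):
        m, ds = trained_toy_model(seed=3)
        empty = ds.subset_rows(np.zeros(ds.n, dtype=bool))
        with pytest.raises(ValueError):
            evaluate(m, empty, provenance=("a", "a"))

    def test_label_permutation_equivariance(self):
        """Permuting the output classes permutes confusion rows and columns
        identically."""
        m, ds = trained_toy_model(seed=4)
        rng = np.random.default_rng(1)
        noisy = ds.df.copy()
        flip = rng.random(len(noisy)) < 0.3
        noisy.loc[flip, "label"] = rng.choice(CLASS_ORDER, size=int(flip.sum()))
        noisy_ds = FeatureDataset(noisy, ds.feature_names, ds.channels)
        base = evaluate(m, noisy_ds, provenance=("a", "a"))

        perm = np.array([2, 0, 3, 4, 1])
        m2 = NetworkModel(
            layer_sizes=m.layer_sizes,
            weights=[w.copy() for w in m.weights[:-1]] + [m.weights[-1][:, perm]],
            biases=[b.copy() for b in m.biases[:-1]] + [m.biases[-1][perm]],
            hidden_activation=m.hidden_activation,
            class_labels=tuple(np.array(m.class_labels)[perm]),
            feature_names=m.feature_names,
            channels=m.channels,
            norm_mean=m.norm_mean,
            norm_scale=m.norm_scale,
        )
        permuted = evaluate(m2, noisy_ds, provenance=("a", "a"))
        assert np.array_equal(permuted.confusion, base.confusion[perm][:, perm])
        assert permuted.accuracy == pytest.approx(base.accuracy)


class TestCrossEvaluate:
    def test_same_dataset_matches_evaluate(self):
        m, ds = trained_toy_model(seed=5)
        a = evaluate(m, ds, provenance=("a", "a"))
        b = cross_evaluate(m, ds, provenance=("a", "a"))
        assert np.array_equal(a.confusion, b.confusion)
        assert a.accuracy == b.accuracy

    def test_missing_feature_rejected(self):
        m, ds = trained_toy_model(seed=6)
        smaller = ds.select(features=("RMS", "MAV"))
        with pytest.raises(FeatureMismatchError):
            cross_evaluate(m, smaller)

    def test_data_normalization_restores_model_state(self):
        m, ds = trained_toy_model(seed=7)
        mu = m.norm_mean.copy()
        cross_evaluate(m, ds, norm_source="data")
        assert np.array_equal(m.norm_mean, mu)


def test_model_json_round_trip(tmp_path):
    m, ds = trained_toy_model(seed=8)
    path = save_model(m, tmp_path / "model.json")
    back = load_model(path)
    assert back.layer_sizes == m.layer_sizes
    for wa, wb in zip(back.weights, m.weights):
        assert np.allclose(wa, wb)
    assert back.feature_names == m.feature_names
    a = evaluate(m, ds, provenance=("a", "a"))
    b = evaluate(back, ds, provenance=("a", "a"))
    assert a.accuracy == b.accuracy
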