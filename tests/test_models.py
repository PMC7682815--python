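import numpy as np
import pytest

from rnafam import (
    EncodingSpec,
    NeuralSequenceClassifier,
    build_bilstm,
    build_improved_cnn,
    build_standard_cnn,
    encode_kmer,
    generate_family_dataset,
    load_classifier,
    save_classifier,
    SyntheticSpec,
)
from rnafam.models import standard_filter_counts
from rnafam.nn import (
    Bidirectional,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    GaussianNoise,
)


def count_layers(net, layer_type):
    return sum(isinstance(l, layer_type) for l in net.layers)


def dense_widths(net):
    return [l.units for l in net.layers if isinstance(l, Dense)]


@pytest.fixture(scope="module")
def toy_problem():
    """Small two-family dataset with strong motifs, 1-mer encoded."""
    spec = SyntheticSpec(
        n_families=2,
        n_per_family=25,
        length_mean_range=(30, 40),
        length_spread=5,
        n_motifs=2,
        motif_length=10,
        insertion_prob=1.0,
        mutation_rate=0.0,
        seed=11,
    )
    ds, _ = generate_family_dataset(spec)
    batch = encode_kmer(ds.records, EncodingSpec("kmer", k=1, max_len=50))
    return batch.array, np.array(ds.labels())


class TestArchitectures:
    def test_standard_cnn_2d_three_blocks(self):
        net = build_standard_cnn((16, 16, 5), n_classes=8, n_conv_layers=3)
        assert count_layers(net, Conv2D) == 3
        assert [l.filters for l in net.layers if isinstance(l, Conv2D)] == [64, 128, 256]
        assert dense_widths(net) == [1000, 500, 8]
        net.build((16, 16, 5), np.random.default_rng(0))
        out = net.forward(np.zeros((2, 16, 16, 5), dtype=np.float32))
        assert out.shape == (2, 8)

    def test_standard_cnn_zero_layers_is_dense_network(self):
        net = build_standard_cnn((200, 5), n_classes=4, n_conv_layers=0)
        assert count_layers(net, Conv1D) == 0 and count_layers(net, Conv2D) == 0
        assert dense_widths(net) == [1000, 500, 4]

    def test_filter_rule(self):
        assert standard_filter_counts(3) == [64, 128, 256]
        assert standard_filter_counts(3, index_base=0) == [32, 64, 128]

    def test_standard_cnn_1d_dropout_rate(self):
        net = build_standard_cnn((100, 17), n_classes=5, n_conv_layers=2)
        drops = [l for l in net.layers if isinstance(l, Dropout)]
        assert len(drops) == 2 and all(d.rate == 0.5 for d in drops)

    def test_invalid_layer_count(self):
        with pytest.raises(ValueError):
            build_standard_cnn((100, 5), 3, n_conv_layers=4)

    def test_improved_cnn_structure(self):
        net = build_improved_cnn((200, 5), n_classes=13)
        assert count_layers(net, Conv1D) == 5
        assert count_layers(net, GaussianNoise) == 2  # after every 2 conv layers
        drops = [l for l in net.layers if isinstance(l, Dropout)]
        assert len(drops) == 1 and drops[0].rate == 0.2
        assert dense_widths(net) == [128, 64, 13]
        net.build((200, 5), np.random.default_rng(0))
        assert net.forward(np.zeros((1, 200, 5), dtype=np.float32)).shape == (1, 13)

    def test_improved_cnn_builds_on_small_grids(self):
        net = build_improved_cnn((15, 15, 4), n_classes=3)
        net.build((15, 15, 4), np.random.default_rng(0))
        assert net.forward(np.zeros((1, 15, 15, 4), dtype=np.float32)).shape == (1, 3)

    def test_improved_cnn_default_optimizer_settings(self):
        clf = NeuralSequenceClassifier(family="cnn_improved")
        assert clf.learning_rate is None  # resolved to AMSGrad @ 5e-4 at fit time

    def test_bilstm_structure(self):
        net = build_bilstm(4, n_classes=6, rnn_nodes=150)
        bi = [l for l in net.layers if isinstance(l, Bidirectional)]
        assert len(bi) == 2 and all(l.units == 150 for l in bi)
        drops = [l for l in net.layers if isinstance(l, Dropout)]
        assert len(drops) == 2 and all(d.rate == 0.2 for d in drops)

    def test_bilstm_rejects_grid_input(self):
        clf = NeuralSequenceClassifier(family="bilstm")
        X = np.zeros((4, 8, 8, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="1D"):
            clf.fit(X, np.array(["a", "b", "a", "b"]))

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown model family"):
            NeuralSequenceClassifier(family="transformer").fit(
                np.zeros((4, 5, 4), dtype=np.float32), np.array(["a", "b", "a", "b"])
            )


class TestTraining:
    def test_memorizes_toy_dataset(self, toy_problem):
        X, y = toy_problem
        clf = NeuralSequenceClassifier(
            n_conv_layers=1, batch_size=16, max_epochs=60, patience=60, seed=0
        )
        clf.fit(X, y)
        assert max(clf.history_["accuracy"]) == 1.0
        assert (clf.predict(X) == y).mean() == 1.0

    def test_fixed_seed_reproduces_history(self, toy_problem):
        X, y = toy_problem
        kwargs = dict(n_conv_layers=1, batch_size=16, max_epochs=3, seed=7)
        h1 = NeuralSequenceClassifier(**kwargs).fit(X, y).history_
        h2 = NeuralSequenceClassifier(**kwargs).fit(X, y).history_
        assert h1["loss"] == h2["loss"]
        assert h1["accuracy"] == h2["accuracy"]

    def test_separable_problem_generalizes(self, rng):
        # linearly separable construction: class decided by channel 0 mean
        n = 120
        X = rng.normal(0, 0.3, size=(n, 20, 4)).astype(np.float32)
        y = np.array(["hi" if i % 2 else "lo" for i in range(n)])
        X[1::2, :, 0] += 1.0
        Xv, yv = X[:40], y[:40]
        clf = NeuralSequenceClassifier(
            n_conv_layers=1, batch_size=16, max_epochs=40, patience=10, seed=1
        )
        clf.fit(X[40:], y[40:], validation_data=(Xv, yv))
        assert (clf.predict(Xv) == yv).mean() > 0.95

    def test_validation_class_missing_from_train_rejected(self, toy_problem):
        X, y = toy_problem
        clf = NeuralSequenceClassifier(max_epochs=1)
        with pytest.raises(ValueError, match="absent"):
            clf.fit(X, y, validation_data=(X[:2], np.array(["novel", "novel"])))

    def test_single_class_rejected(self):
        clf = NeuralSequenceClassifier(max_epochs=1)
        with pytest.raises(ValueError, match="2 classes"):
            clf.fit(np.zeros((3, 5, 4), dtype=np.float32), np.array(["a", "a", "a"]))

    def test_monitored_loss_decreases_at_checkpoints(self, toy_problem):
        X, y = toy_problem
        clf = NeuralSequenceClassifier(
            n_conv_layers=1, batch_size=16, max_epochs=20, patience=20, seed=0
        )
        clf.fit(X, y, validation_data=(X, y))
        val = clf.history_["val_loss"]
        checkpoints = [v for i, v in enumerate(val) if v == min(val[: i + 1])]
        assert checkpoints == sorted(checkpoints, reverse=True)

    def test_bilstm_accepts_variable_length_batches(self, rng):
        X = [rng.normal(size=(int(rng.integers(5, 15)), 4)).astype(np.float32) for _ in range(30)]
        y = np.array(["a", "b"] * 15)
        for i, x in enumerate(X):  # plant a separable signal
            if y[i] == "a":
                x[:, 0] += 1.5
        clf = NeuralSequenceClassifier(
            family="bilstm", rnn_nodes=8, batch_size=8, max_epochs=30, patience=30, seed=2
        )
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (30, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (clf.predict(X) == y).mean() >= 0.9


@pytest.fixture(scope="module")
def fitted(toy_problem):
    X, y = toy_problem
    clf = NeuralSequenceClassifier(
        n_conv_layers=1, batch_size=16, max_epochs=25, patience=25, seed=3
    )
    return clf.fit(X, y), X, y


class TestPrediction:
    def test_rows_sum_to_one(self, fitted):
        clf, X, _ = fitted
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_get_identical_rows(self, fitted):
        clf, X, _ = fitted
        batch = np.stack([X[0], X[1], X[0]])
        proba = clf.predict_proba(batch)
        assert np.array_equal(proba[0], proba[2])

    def test_shape_mismatch_rejected(self, fitted):
        clf, _, _ = fitted
        with pytest.raises(ValueError, match="shape"):
            clf.predict_proba(np.zeros((2, 9, 5), dtype=np.float32))

    def test_class_order_is_sorted(self, fitted):
        clf, _, y = fitted
        assert list(clf.classes_) == sorted(set(y))

    def test_save_load_round_trip(self, fitted, tmp_path):
        clf, X, _ = fitted
        save_classifier(clf, tmp_path / "ckpt")
        back = load_classifier(tmp_path / "ckpt")
        assert np.allclose(back.predict_proba(X), clf.predict_proba(X), atol=1e-6)
        assert list(back.classes_) == list(clf.classes_)
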