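"""Classifier architectures for encoded ncRNA sequences.

Three families are provided, all trained with categorical cross-entropy:

* ``cnn_standard`` — up to 3 convolution blocks (kernel 3, ReLU,
  max-pooling, 50% dropout), 1D on k-mer inputs and 2D on curve grids,
  with 32*2^i filters at block i, followed by dense layers of 1000 and
  500 rectified units and a softmax output. Zero blocks degenerate to a
  dense-only network. Optimized with Adam.
* ``cnn_improved`` — 5 convolution layers interleaved with batch
  normalization, Leaky ReLU and max-pooling; additive Gaussian noise
  after every 2 convolution layers; 20% dropout after the last; dense
  layers of 128 and 64 units; optimized with AMSGrad at learning rate
  5e-4.
* ``bilstm`` — two bidirectional LSTM layers (50/100/150 units)
  alternating with 20% dropout over variable-length, unpadded k-mer
  encodings, followed by a dense layer and softmax.

The public surface is the sklearn-style :class:`NeuralSequenceClassifier`;
the ``build_*`` functions are thin architecture factories over
:mod:`rnafam.nn`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import (
    BatchNorm,
    Bidirectional,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GaussianNoise,
    LeakyReLU,
    MaxPool1D,
    MaxPool2D,
    ReLU,
    Sequential,
    fit_network,
    forward_proba,
)

CHECKPOINT_FORMAT_VERSION = 1

IMPROVED_FILTERS = (32, 32, 64, 64, 128)
IMPROVED_NOISE_STD = 0.1


def standard_filter_counts(n_conv_layers: int, index_base: int = 1) -> list[int]:
    """Filters per convolution block: 32 * 2^i with i starting at index_base."""
    return [32 * 2 ** (index_base + j) for j in range(n_conv_layers)]


def build_standard_cnn(
    input_shape: tuple,
    n_classes: int,
    n_conv_layers: int = 3,
    filter_index_base: int = 1,
) -> Sequential:
    """Standard CNN: conv blocks + dense 1000/500 + softmax logits."""
    if n_conv_layers not in (0, 1, 2, 3):
        raise ValueError("n_conv_layers must be in {0,1,2,3}")
    if len(input_shape) == 2:
        conv, pool = Conv1D, MaxPool1D
    elif len(input_shape) == 3:
        conv, pool = Conv2D, MaxPool2D
    else:
        raise ValueError(f"unsupported input shape {input_shape}")
    layers: list = []
    for filters in standard_filter_counts(n_conv_layers, filter_index_base):
        layers += [conv(filters, kernel=3), ReLU(), pool(2), Dropout(0.5)]
    layers += [Flatten(), Dense(1000), ReLU(), Dense(500), ReLU(), Dense(n_classes)]
    return Sequential(layers)


def build_improved_cnn(input_shape: tuple, n_classes: int) -> Sequential:
    """Improved CNN: 5 conv/batch-norm/LeakyReLU/pool layers + dense 128/64."""
    if len(input_shape) == 2:
        conv, pool = Conv1D, MaxPool1D
    elif len(input_shape) == 3:
        conv, pool = Conv2D, MaxPool2D
    else:
        raise ValueError(f"unsupported input shape {input_shape}")
    layers: list = []
    for i, filters in enumerate(IMPROVED_FILTERS, start=1):
        layers += [conv(filters, kernel=3), BatchNorm(), LeakyReLU(), pool(2)]
        if i % 2 == 0:
            layers.append(GaussianNoise(IMPROVED_NOISE_STD))
    layers.append(Dropout(0.2))
    layers += [Flatten(), Dense(128), ReLU(), Dense(64), ReLU(), Dense(n_classes)]
    return Sequential(layers)


def build_bilstm(n_channels: int, n_classes: int, rnn_nodes: int = 150) -> Sequential:
    """Two bidirectional LSTM layers alternating with 20% dropout."""
    return Sequential(
        [
            Bidirectional(rnn_nodes, return_sequences=True),
            Dropout(0.2),
            Bidirectional(rnn_nodes, return_sequences=False),
            Dropout(0.2),
            Dense(rnn_nodes),
            ReLU(),
            Dense(n_classes),
        ]
    )


class NeuralSequenceClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style front end over the CNN/BiLSTM architectures.

    Parameters
    ----------
    family : {"cnn_standard", "cnn_improved", "bilstm"}
    n_conv_layers : int
        Convolution blocks for the standard CNN (0 gives a dense network).
    rnn_nodes : int
        Units per direction in each bidirectional LSTM layer.
    filter_index_base : int
        First exponent i in the 32*2^i filter rule (default 1: 64/128/256).
    learning_rate : float or None
        None selects the family default (1e-3 Adam; 5e-4 AMSGrad improved).
    batch_size, max_epochs, patience : int
        Minibatch size, epoch cap, and early-stopping patience on
        validation loss.
    lr_schedule : {None, "cosine"}
        Constant learning rate (default) or 2-epoch warmup followed by
        cosine decay to a tenth of the peak over ``max_epochs``.
    max_seconds : float or None
        Optional wall-clock training budget; training stops after the
        epoch in which it is exhausted and restores the best weights.
    seed : int
        Seeds weight initialization, shuffling, dropout and noise.

    Inputs ``X`` are encoded arrays with a trailing channel axis —
    (n, positions, channels) for 1D, (n, side, side, channels) for 2D —
    or, for the BiLSTM family, a list of per-sequence (T_i, channels)
    arrays with no padding.
    """

    def __init__(
        self,
        family: str = "cnn_standard",
        n_conv_layers: int = 3,
        rnn_nodes: int = 150,
        filter_index_base: int = 1,
        learning_rate: float | None = None,
        batch_size: int = 128,
        max_epochs: int = 100,
        patience: int = 10,
        lr_schedule: str | None = None,
        max_seconds: float | None = None,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.family = family
        self.n_conv_layers = n_conv_layers
        self.rnn_nodes = rnn_nodes
        self.filter_index_base = filter_index_base
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr_schedule = lr_schedule
        self.max_seconds = max_seconds
        self.seed = seed
        self.verbose = verbose

    # -- construction -------------------------------------------------
    def _build(self, input_shape: tuple, n_classes: int) -> Sequential:
        if self.family == "cnn_standard":
            return build_standard_cnn(
                input_shape, n_classes, self.n_conv_layers, self.filter_index_base
            )
        if self.family == "cnn_improved":
            return build_improved_cnn(input_shape, n_classes)
        if self.family == "bilstm":
            if len(input_shape) != 2:
                raise ValueError("bilstm accepts 1D (time, channels) inputs only")
            return build_bilstm(input_shape[1], n_classes, self.rnn_nodes)
        raise ValueError(f"unknown model family {self.family!r}")

    @staticmethod
    def _sample_shape(X) -> tuple:
        if isinstance(X, np.ndarray):
            return tuple(X.shape[1:])
        # ragged list of (T_i, C): time axis is unconstrained
        return (None, X[0].shape[1])

    def _onehot(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes_)}
        out = np.zeros((len(y), len(self.classes_)), dtype=np.float32)
        for i, label in enumerate(y):
            out[i, index[label]] = 1.0
        return out

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, validation_data: tuple | None = None):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least 2 classes")
        if validation_data is not None:
            Xval, yval = validation_data
            missing = set(np.asarray(yval).tolist()) - set(self.classes_.tolist())
            if missing:
                raise ValueError(
                    f"validation classes absent from training data: {sorted(missing)}"
                )
        shape = self._sample_shape(X)
        if self.family == "bilstm" and len(shape) != 2:
            raise ValueError("bilstm accepts 1D (time, channels) inputs only")
        rng = np.random.default_rng(self.seed)
        net = self._build(shape, len(self.classes_)).build(shape, rng)
        lr = self.learning_rate
        amsgrad = self.family == "cnn_improved"
        if lr is None:
            lr = 5e-4 if amsgrad else 1e-3
        val = None
        if validation_data is not None:
            val = (Xval, self._onehot(np.asarray(yval)))
        self.history_ = fit_network(
            net,
            X,
            self._onehot(y),
            val,
            lr=lr,
            amsgrad=amsgrad,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            lr_schedule=self.lr_schedule,
            max_seconds=self.max_seconds,
            rng=rng,
            verbose=self.verbose,
        )
        self.model_ = net
        self.input_shape_ = shape
        return self

    def _check_input(self, X) -> None:
        shape = self._sample_shape(X)
        expected = self.input_shape_
        if len(shape) != len(expected) or any(
            e is not None and s != e for s, e in zip(shape, expected)
        ):
            raise ValueError(f"input shape {shape} does not match fitted {expected}")

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self._check_input(X)
        return forward_proba(self.model_, X, mode="eval", batch_size=max(self.batch_size, 256))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def save_classifier(clf: NeuralSequenceClassifier, directory: str | Path) -> None:
    """Persist a fitted classifier: weights (npz) + plain-text metadata."""
    check_is_fitted(clf, "model_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = clf.model_.state_arrays()
    np.savez(directory / "weights.npz", *arrays)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "params": clf.get_params(),
        "classes": [str(c) for c in clf.classes_],
        "input_shape": list(clf.input_shape_),
        "history": {k: list(map(float, v)) for k, v in clf.history_.items()},
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_classifier(directory: str | Path) -> NeuralSequenceClassifier:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError("unsupported checkpoint format version")
    clf = NeuralSequenceClassifier(**meta["params"])
    clf.classes_ = np.asarray(meta["classes"])
    clf.input_shape_ = tuple(None if s is None else int(s) for s in meta["input_shape"])
    clf.history_ = {k: list(v) for k, v in meta["history"].items()}
    rng = np.random.default_rng(0)
    net = clf._build(clf.input_shape_, len(clf.classes_)).build(clf.input_shape_, rng)
    with np.load(directory / "weights.npz") as data:
        arrays = [data[k] for k in data.files]
    net.load_state_arrays(arrays)
    clf.model_ = net
    return clf
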