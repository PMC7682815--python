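"""Training loop: minibatch cross-entropy optimization with early stopping."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .layers import Sequential
from .optim import Adam


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    loss = float(-(y_onehot * np.log(p + 1e-12)).sum(axis=1).mean())
    dlogits = (p - y_onehot) / logits.shape[0]
    return loss, dlogits.astype(np.float32), p


def _make_batch(X, idx: np.ndarray):
    """Dense slice for array inputs; padded stack + mask for ragged lists."""
    if isinstance(X, np.ndarray):
        return X[idx], None
    samples = [X[i] for i in idx]
    T = max(s.shape[0] for s in samples)
    C = samples[0].shape[1]
    batch = np.zeros((len(samples), T, C), dtype=np.float32)
    mask = np.zeros((len(samples), T), dtype=bool)
    for j, s in enumerate(samples):
        batch[j, : s.shape[0]] = s
        mask[j, : s.shape[0]] = True
    return batch, mask


def forward_proba(net: Sequential, X, mode: str = "eval", rng=None, batch_size: int = 256):
    """Class probabilities for a full dataset, evaluated in minibatches."""
    n = len(X)
    out = []
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        xb, mask = _make_batch(X, idx)
        out.append(softmax(net.forward(xb, mode=mode, rng=rng, mask=mask)))
    return np.concatenate(out, axis=0)


def _dataset_loss(net: Sequential, X, y_onehot: np.ndarray, batch_size: int = 256):
    p = forward_proba(net, X, mode="eval", batch_size=batch_size)
    loss = float(-(y_onehot * np.log(p + 1e-12)).sum(axis=1).mean())
    acc = float((p.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
    return loss, acc


def fit_network(
    net: Sequential,
    X,
    y_onehot: np.ndarray,
    validation_data: tuple | None = None,
    *,
    lr: float = 1e-3,
    amsgrad: bool = False,
    batch_size: int = 128,
    max_epochs: int = 100,
    patience: int = 10,
    lr_schedule: str | None = None,
    max_seconds: float | None = None,
    rng: np.random.Generator | None = None,
    verbose: int = 0,
) -> dict[str, list[float]]:
    """Optimize categorical cross-entropy with Adam (or AMSGrad).

    Early stopping monitors validation loss with the given patience and the
    best-scoring weights are restored before returning. Without validation
    data, training loss is monitored instead. ``lr_schedule="cosine"``
    applies a 2-epoch linear warmup followed by cosine decay of the
    learning rate to 1/10 of its peak over ``max_epochs`` (the default is
    a constant rate). ``max_seconds`` bounds wall-clock training time:
    when the budget is exhausted the loop stops after the current epoch
    and the best weights so far are restored, so a run degrades gracefully
    on slower hardware instead of overshooting. Returns the per-epoch
    history (loss, accuracy, and validation figures when available).
    """
    import time

    start_time = time.monotonic()
    if rng is None:
        rng = np.random.default_rng(0)
    if lr_schedule not in (None, "cosine"):
        raise ValueError("lr_schedule must be None or 'cosine'")
    opt = Adam(net.params(), lr=lr, amsgrad=amsgrad)
    n = len(X)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if validation_data is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    best_loss = np.inf
    best_state = None
    best_epoch = -1
    since_best = 0
    for epoch in range(max_epochs):
        if lr_schedule == "cosine":
            warmup = 2
            if epoch < warmup:
                opt.lr = lr * (epoch + 1) / warmup
            else:
                frac = (epoch - warmup) / max(1, max_epochs - warmup)
                opt.lr = 0.1 * lr + 0.45 * lr * (1.0 + np.cos(np.pi * frac))
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, mask = _make_batch(X, idx)
            yb = y_onehot[idx]
            net.zero_grad()
            logits = net.forward(xb, mode="train", rng=rng, mask=mask)
            loss, dlogits, p = softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((p.argmax(axis=1) == yb.argmax(axis=1)).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        if validation_data is not None:
            val_loss, val_acc = _dataset_loss(net, *validation_data)
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)
            monitored = val_loss
        else:
            monitored = history["loss"][-1]
        if verbose:
            msg = f"epoch {epoch + 1}: loss={history['loss'][-1]:.4f} acc={history['accuracy'][-1]:.4f}"
            if validation_data is not None:
                msg += f" val_loss={history['val_loss'][-1]:.4f} val_acc={history['val_accuracy'][-1]:.4f}"
            print(msg)
        if monitored < best_loss - 1e-6:
            best_loss = monitored
            best_state = net.state_arrays()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
        if max_seconds is not None and time.monotonic() - start_time > max_seconds:
            break
    if best_state is not None:
        net.load_state_arrays(best_state)
    history["best_epoch"] = [float(best_epoch)]
    return history
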