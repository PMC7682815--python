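"""Monte Carlo Dropout uncertainty estimation and rejection.

A trained dropout network is run ``n_mc`` times on the same input with
dropout active at inference, giving per-input samples of class-probability
vectors p_ik (i = 1..N_mc, k = 1..C). Two scalar uncertainty estimators
are derived from the sample:

* Information Entropy ``H = -sum_k p̄_k log2(p̄_k + eps)`` of the mean
  distribution p̄, in bits; high H signals an uncertain (possibly
  non-functional) input. Default rejection threshold: one third of the
  maximal entropy, (1/3) log2 C.
* Top Difference ``D = p̄_k1 - c*sigma_k1 - (p̄_k2 + c*sigma_k2)`` for the
  two classes with the largest mean probabilities, with c = 0.6 by
  default; D < 0 signals uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import NeuralSequenceClassifier
from .nn import forward_proba

DEFAULT_N_MC = 50
DEFAULT_C = 0.6
DEFAULT_EPS = 1e-12


@dataclass
class MCPosterior:
    """The N_mc x C matrix of class probabilities for one input."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("samples must be an N_mc x C matrix with N_mc >= 2")
        sums = self.samples.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("each Monte Carlo sample must sum to 1")

    @property
    def n_mc(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return self.samples.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.samples.std(axis=0)


@dataclass(frozen=True)
class UncertaintyScores:
    H: float
    D: float
    c: float = DEFAULT_C
    eps: float = DEFAULT_EPS


def mc_dropout_predict(
    classifier: NeuralSequenceClassifier,
    X,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
    dropout_active: bool = True,
) -> list[MCPosterior]:
    """Run ``n_mc`` dropout-perturbed forward passes per input.

    Dropout layers stay active at their training rates (inverted-dropout
    convention, so mean activation is preserved); batch normalization uses
    inference statistics. Deterministic under the seed. Raises if the model
    has no dropout layer, since the posterior would be degenerate.
    ``dropout_active=False`` turns the stochasticity off (all passes
    identical, zero Monte Carlo variance) for diagnostics.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    if not classifier.model_.has_dropout():
        raise ValueError("Monte Carlo Dropout requires a model with dropout layers")
    rng = np.random.default_rng(seed)
    mode = "mc" if dropout_active else "eval"
    passes = np.stack(
        [forward_proba(classifier.model_, X, mode=mode, rng=rng) for _ in range(n_mc)]
    )  # (n_mc, n, C)
    return [MCPosterior(passes[:, i, :]) for i in range(passes.shape[1])]


def information_entropy(posterior: MCPosterior, eps: float = DEFAULT_EPS) -> float:
    """Shannon entropy (bits) of the Monte Carlo mean class distribution."""
    p = posterior.mean
    return float(-(p * np.log2(p + eps)).sum())


def top_difference(posterior: MCPosterior, c: float = DEFAULT_C) -> float:
    """Gap between the two top mean classes, penalized by c times their
    Monte Carlo standard deviations."""
    if posterior.n_classes < 2:
        raise ValueError("top difference requires at least 2 classes")
    mean = posterior.mean
    std = posterior.std
    k1, k2 = np.argsort(mean)[::-1][:2]
    return float(mean[k1] - c * std[k1] - (mean[k2] + c * std[k2]))


def uncertainty_scores(
    posterior: MCPosterior, c: float = DEFAULT_C, eps: float = DEFAULT_EPS
) -> UncertaintyScores:
    return UncertaintyScores(
        H=information_entropy(posterior, eps), D=top_difference(posterior, c), c=c, eps=eps
    )


def entropy_threshold(n_classes: int) -> float:
    """Default entropy rejection threshold: one third of the maximal entropy."""
    return math.log2(n_classes) / 3.0


def rejection_decision(
    scores: UncertaintyScores,
    n_classes: int,
    estimator: str = "entropy",
    threshold: float | None = None,
) -> bool:
    """True = reject the sample as uncertain/non-functional.

    The entropy estimator rejects when H exceeds the threshold (default
    (1/3) log2 C); the top-difference estimator rejects when D falls below
    the threshold (default 0).
    """
    if estimator == "entropy":
        if threshold is None:
            threshold = entropy_threshold(n_classes)
        return scores.H > threshold
    if estimator == "topdiff":
        if threshold is None:
            threshold = 0.0
        return scores.D < threshold
    raise ValueError(f"unknown estimator {estimator!r}; use 'entropy' or 'topdiff'")


def rejection_table(
    classifier: NeuralSequenceClassifier,
    X,
    ids: list[str] | None = None,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
    c: float = DEFAULT_C,
    eps: float = DEFAULT_EPS,
    estimator: str = "entropy",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-record MC Dropout summary: H, D, decision and predicted class."""
    posteriors = mc_dropout_predict(classifier, X, n_mc=n_mc, seed=seed)
    n_classes = len(classifier.classes_)
    rows = []
    for i, post in enumerate(posteriors):
        sc = uncertainty_scores(post, c=c, eps=eps)
        rows.append(
            {
                "id": ids[i] if ids is not None else str(i),
                "H": sc.H,
                "D": sc.D,
                "rejected": rejection_decision(sc, n_classes, estimator, threshold),
                "predicted": str(classifier.classes_[int(np.argmax(post.mean))]),
            }
        )
    return pd.DataFrame(rows)
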