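"""End-to-end experiment pipeline on synthetic family data.

Chains the package stages — generate, (optionally) add boundary noise,
homology-aware split, encode, train, evaluate, and MC-Dropout rejection —
at a scale that runs on a single CPU core in minutes. Used by the
reproduction script and the end-to-end tests; also a template for running
the same workflow on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import EncodingSpec, encode
from .io import LabeledDataset
from .metrics import MetricsReport, classification_report, roc_auc
from .models import NeuralSequenceClassifier
from .prep import NoiseSpec, SplitConfig, add_boundary_noise, similarity_aware_split
from .synthetic import SyntheticSpec, generate_family_dataset, make_negatives
from .uncertainty import (
    entropy_threshold,
    information_entropy,
    mc_dropout_predict,
    top_difference,
)


@dataclass
class ExperimentResult:
    accuracy: float
    report: MetricsReport
    classifier: NeuralSequenceClassifier
    encoding_spec: EncodingSpec
    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset
    noise_percent: float


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_family_experiment(
    seed: int,
    representation: str = "kmer",
    k: int = 1,
    padding: str = "new",
    noise_percent: float = 0.0,
    data_spec: SyntheticSpec | None = None,
    n_conv_layers: int = 1,
    learning_rate: float = 2e-3,
    batch_size: int = 64,
    max_epochs: int = 30,
    patience: int = 8,
    lr_schedule: str | None = "cosine",
    max_seconds: float | None = None,
) -> ExperimentResult:
    """Generate-split-train-evaluate one configuration.

    With ``noise_percent > 0`` every sequence receives composition-matched
    boundary flanks *before* splitting, and the encoder's maximum length
    grows to fit the extended sequences — the whole pipeline, including
    training, sees noisy data. Returns held-out test metrics and the
    fitted classifier.
    """
    rng = np.random.default_rng(seed)
    data_spec = data_spec or SyntheticSpec.easy(seed=_sub_seed(rng))
    dataset, _ = generate_family_dataset(data_spec)
    if noise_percent > 0:
        dataset = LabeledDataset(
            [
                add_boundary_noise(r, NoiseSpec(percent=noise_percent, seed=_sub_seed(rng)))
                for r in dataset
            ]
        )
    split = similarity_aware_split(dataset, SplitConfig(seed=_sub_seed(rng)))
    max_len = max(r.length for r in dataset)
    if noise_percent == 0:
        max_len = max(max_len, data_spec.length_bounds[1])
    espec = EncodingSpec(
        representation, k=k, max_len=max_len, padding=padding, seed=_sub_seed(rng)
    )
    X = {part: encode(ds.records, espec).array for part, ds in
         zip(("train", "val", "test"), split)}
    y = {part: np.array(ds.labels()) for part, ds in zip(("train", "val", "test"), split)}
    clf = NeuralSequenceClassifier(
        family="cnn_standard",
        n_conv_layers=n_conv_layers,
        learning_rate=learning_rate,
        batch_size=batch_size,
        max_epochs=max_epochs,
        patience=patience,
        lr_schedule=lr_schedule,
        max_seconds=max_seconds,
        seed=_sub_seed(rng),
    )
    clf.fit(X["train"], y["train"], validation_data=(X["val"], y["val"]))
    pred = clf.predict(X["test"])
    report = classification_report(y["test"], pred, classes=list(clf.classes_))
    return ExperimentResult(
        accuracy=report.accuracy,
        report=report,
        classifier=clf,
        encoding_spec=espec,
        train=split.train,
        validation=split.validation,
        test=split.test,
        noise_percent=noise_percent,
    )


def run_rejection_experiment(
    result: ExperimentResult,
    seed: int,
    n_mc: int = 50,
    c: float = 0.6,
) -> dict[str, float]:
    """MC-Dropout rejection on the doubled test set of an experiment.

    The test set is doubled with one dinucleotide-preserving shuffle per
    sequence; functional-vs-decoy separation is scored by ROC-AUC of -H
    and D, and classification accuracy on the functional test set is
    compared before and after entropy-threshold rejection.
    """
    rng = np.random.default_rng(seed)
    clf = result.classifier
    espec = result.encoding_spec
    decoys = make_negatives(result.test, seed=_sub_seed(rng))
    X_pos = encode(result.test.records, espec).array
    X_neg = encode(decoys.records, espec).array
    posts_pos = mc_dropout_predict(clf, X_pos, n_mc=n_mc, seed=_sub_seed(rng))
    posts_neg = mc_dropout_predict(clf, X_neg, n_mc=n_mc, seed=_sub_seed(rng))
    H = np.array([information_entropy(p) for p in posts_pos + posts_neg])
    D = np.array([top_difference(p, c=c) for p in posts_pos + posts_neg])
    labels = np.array([1] * len(posts_pos) + [0] * len(posts_neg))
    auc_entropy = roc_auc(-H, labels)
    auc_topdiff = roc_auc(D, labels)

    y_true = np.array(result.test.labels())
    pred = clf.classes_[
        np.argmax(np.stack([p.mean for p in posts_pos]), axis=1)
    ]
    threshold = entropy_threshold(len(clf.classes_))
    accepted = H[: len(posts_pos)] <= threshold
    acc_unfiltered = float((pred == y_true).mean())
    if accepted.any():
        acc_after = float((pred[accepted] == y_true[accepted]).mean())
    else:
        acc_after = float("nan")
    return {
        "auc_entropy": auc_entropy,
        "auc_topdiff": auc_topdiff,
        "accuracy_unfiltered": acc_unfiltered,
        "accuracy_after_entropy_rejection": acc_after,
        "rejected_fraction": float(1.0 - accepted.mean()),
        "n_test": int(len(posts_pos)),
    }
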