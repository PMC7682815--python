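"""Dataset preparation: homology-aware splitting, boundary noise,
dinucleotide-preserving shuffling, and the length-predictability screen.

Random splits of homologous sequence families overstate generalization,
because near-identical homologs land on both sides of the split. The
splitter here stratifies per class and then repairs the draw so that every
validation/test sequence has normalized similarity below a threshold
(default 0.50) to every same-class training sequence.

Boundary noise models uncertainty about where a transcript starts and
ends: flanks whose nucleotide and dinucleotide composition match the
source sequence are appended on both sides. Dinucleotide-preserving
shuffling (the Eulerian-path construction of Altschul & Erickson) turns a
sequence into a compositionally matched non-functional decoy.
"""

from __future__ import annotations

import collections
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .io import LabeledDataset, SequenceRecord

ALPHABET = "ACGT"


@dataclass(frozen=True)
class SplitConfig:
    """Fractions, similarity threshold and seed for the homology-aware split."""

    fractions: tuple[float, float, float] = (0.84, 0.08, 0.08)
    similarity_threshold: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Boundary-noise amount (percent of sequence length) and seed."""

    percent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.percent < 0:
            raise ValueError("noise percent must be >= 0")


@dataclass
class SplitResult:
    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def normalized_similarity(seq_a: str, seq_b: str) -> float:
    """Similarity = 1 - normalized Hamming distance, in [0, 1].

    Mismatches are counted position-wise; positions beyond the shorter
    sequence count as mismatches, and the count is normalized by the longer
    length. Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) < len(seq_b):
        seq_a, seq_b = seq_b, seq_a
    longer = len(seq_a)
    mismatches = longer - len(seq_b)
    mismatches += sum(a != b for a, b in zip(seq_a, seq_b))
    return 1.0 - mismatches / longer


def _pairwise_max_similarity(queries: list[str], pool: list[str]) -> np.ndarray:
    """Max similarity of each query against a pool, vectorized over positions."""
    if not pool:
        return np.zeros(len(queries))
    max_len = max(max(len(s) for s in queries), max(len(s) for s in pool))
    def to_mat(seqs):
        m = np.zeros((len(seqs), max_len), dtype=np.uint8)
        lens = np.array([len(s) for s in seqs])
        for i, s in enumerate(seqs):
            m[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        return m, lens
    qm, ql = to_mat(queries)
    pm, pl = to_mat(pool)
    out = np.zeros(len(queries))
    for i in range(len(queries)):
        # matches only count inside the overlap (padding bytes are 0 and
        # never match a base); normalize by the longer length
        matches = (qm[i][None, :] == pm).sum(axis=1) - (max_len - np.maximum(ql[i], pl))
        sim = 1.0 - (np.maximum(ql[i], pl) - matches) / np.maximum(ql[i], pl)
        out[i] = sim.max()
    return out


def similarity_aware_split(dataset: LabeledDataset, config: SplitConfig) -> SplitResult:
    """Stratified train/validation/test split with a homology repair pass.

    Each class is shuffled and cut into train/validation/test by the
    configured fractions. Any validation or test record whose similarity to
    some same-class training record reaches the threshold is moved into
    train; the pass repeats until stable, so adding violators to train
    cannot leave a stale assignment. Classes with fewer than 3 records are
    placed wholly in train with a warning. Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    f_train, f_val, f_test = config.fractions
    assignment: dict[int, str] = {}
    max_sims: dict[int, float] = {}
    for label in dataset.classes:
        idx = dataset.by_class()[label]
        if len(idx) < 3:
            warnings.warn(
                f"class {label!r} has fewer than 3 records; placed wholly in train"
            )
            for i in idx:
                assignment[i] = "train"
                max_sims[i] = math.nan
            continue
        perm = list(rng.permutation(len(idx)))
        shuffled = [idx[j] for j in perm]
        n = len(shuffled)
        n_val = int(round(f_val * n))
        n_test = int(round(f_test * n))
        n_train = n - n_val - n_test
        parts = {
            "train": shuffled[:n_train],
            "validation": shuffled[n_train : n_train + n_val],
            "test": shuffled[n_train + n_val :],
        }
        while True:
            train_seqs = [dataset[i].sequence for i in parts["train"]]
            moved = False
            for part in ("validation", "test"):
                keep: list[int] = []
                for i in parts[part]:
                    sim = _pairwise_max_similarity([dataset[i].sequence], train_seqs)[0]
                    max_sims[i] = sim
                    if sim >= config.similarity_threshold:
                        parts["train"].append(i)
                        moved = True
                    else:
                        keep.append(i)
                parts[part] = keep
            if not moved:
                break
        for part, members in parts.items():
            for i in members:
                assignment[i] = part
                max_sims.setdefault(i, math.nan)
    unlabeled = [i for i, r in enumerate(dataset) if r.label is None]
    for i in unlabeled:
        assignment[i] = "train"
        max_sims[i] = math.nan
    audit = pd.DataFrame(
        {
            "id": [dataset[i].id for i in sorted(assignment)],
            "label": [dataset[i].label for i in sorted(assignment)],
            "assignment": [assignment[i] for i in sorted(assignment)],
            "max_similarity_to_train": [max_sims[i] for i in sorted(assignment)],
        }
    )
    def collect(part: str) -> LabeledDataset:
        return dataset.subset(i for i in range(len(dataset)) if assignment[i] == part)
    return SplitResult(collect("train"), collect("validation"), collect("test"), audit)


def _composition(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Nucleotide frequencies and conditional dinucleotide transition matrix."""
    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    counts = np.zeros(4)
    trans = np.zeros((4, 4))
    for b in sequence:
        counts[base_idx[b]] += 1
    for a, b in zip(sequence, sequence[1:]):
        trans[base_idx[a], base_idx[b]] += 1
    freqs = counts / counts.sum()
    rows = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(rows > 0, trans / rows, freqs[None, :])
    return freqs, cond


def _markov_flank(n: int, freqs: np.ndarray, cond: np.ndarray, rng: np.random.Generator) -> str:
    if n == 0:
        return ""
    # inverse-CDF sampling from one vector of uniforms (fast for long flanks)
    u = rng.random(n)
    cum_init = np.cumsum(freqs)
    cum_cond = np.cumsum(cond, axis=1)
    state = min(int(np.searchsorted(cum_init, u[0] * cum_init[-1])), 3)
    out = [state]
    for i in range(1, n):
        row = cum_cond[state]
        state = min(int(np.searchsorted(row, u[i] * row[-1])), 3)
        out.append(state)
    return "".join(ALPHABET[i] for i in out)


def add_boundary_noise(record: SequenceRecord, spec: NoiseSpec) -> SequenceRecord:
    """Append composition-matched flanks totalling percent/100 of the length.

    The total flank length is round-half-up of percent/100 x N, split
    between the 5' and 3' ends uniformly at random. Flank bases follow a
    first-order Markov chain whose initial distribution is the sequence's
    nucleotide frequency and whose transitions are its conditional
    dinucleotide frequencies, so nucleotide and dinucleotide composition
    are preserved in expectation. The original sequence appears intact and
    contiguous between the flanks.
    """
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError("boundary noise requires a sequence of length >= 2")
    if spec.percent == 0:
        return record
    rng = np.random.default_rng(spec.seed)
    total = math.floor(spec.percent / 100.0 * len(seq) + 0.5)
    n5 = int(rng.integers(0, total + 1))
    n3 = total - n5
    freqs, cond = _composition(seq)
    flank5 = _markov_flank(n5, freqs, cond, rng)
    flank3 = _markov_flank(n3, freqs, cond, rng)
    return record.with_sequence(flank5 + seq + flank3)


def dinucleotide_counts(sequence: str) -> dict[str, int]:
    return dict(collections.Counter(a + b for a, b in zip(sequence, sequence[1:])))


def dinucleotide_shuffle(record: SequenceRecord | str, seed: int = 0) -> SequenceRecord | str:
    """Shuffle a sequence preserving its exact dinucleotide multiset.

    Altschul-Erickson Eulerian-path construction: the sequence is viewed as
    an Eulerian walk on the multigraph whose edges are its adjacent base
    pairs. A random last-edge arborescence toward the final base is drawn
    (rejection sampling), the remaining out-edges of every base are
    permuted, and the walk is replayed. The result has the same length,
    first base, last base and dinucleotide counts as the input.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if len(seq) < 2:
        return record
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = collections.defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(10_000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        # the chosen last edges must form a tree rooted at the final base
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop on a 4-letter alphabet terminates
        raise RuntimeError("failed to sample a valid last-edge arborescence")
    shuffled_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        targets = list(targets)
        if v in last_edge:
            targets.remove(last_edge[v])
            perm = rng.permutation(len(targets))
            targets = [targets[i] for i in perm] + [last_edge[v]]
        else:
            perm = rng.permutation(len(targets))
            targets = [targets[i] for i in perm]
        shuffled_edges[v] = targets
    pos = {v: 0 for v in edges}
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    result = "".join(out)
    if isinstance(record, SequenceRecord):
        return record.with_sequence(result)
    return result


def screen_length_predictable(
    dataset: LabeledDataset,
    f1_cutoff: float = 0.80,
    folds: int = 10,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Flag classes a length-only decision tree predicts too well.

    Runs ``folds``-fold stratified cross-validation of a decision tree whose
    sole feature is sequence length and averages per-class F1 over the folds
    in which the class appears. Classes with mean F1 above ``f1_cutoff``
    are returned for removal by the caller, together with the per-class
    score table.
    """
    classes = dataset.classes
    if len(classes) < 2:
        raise ValueError("length screen requires at least 2 classes")
    labeled = [r for r in dataset if r.label is not None]
    X = np.array([[r.length] for r in labeled], dtype=float)
    y = np.array([r.label for r in labeled])
    n_splits = min(folds, min(collections.Counter(y).values()))
    if n_splits < 2:
        raise ValueError("every class needs at least 2 records for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores: dict[str, list[float]] = {c: [] for c in classes}
    for train_idx, test_idx in skf.split(X, y):
        tree = DecisionTreeClassifier(random_state=seed)
        tree.fit(X[train_idx], y[train_idx])
        pred = tree.predict(X[test_idx])
        present = sorted(set(y[test_idx]))
        fold_f1 = f1_score(y[test_idx], pred, labels=present, average=None, zero_division=0)
        for c, s in zip(present, fold_f1):
            scores[c].append(float(s))
    table = pd.DataFrame(
        {
            "label": classes,
            "mean_f1": [float(np.mean(scores[c])) if scores[c] else math.nan for c in classes],
            "n_folds": [len(scores[c]) for c in classes],
        }
    )
    flagged = [c for c, m in zip(table["label"], table["mean_f1"]) if m > f1_cutoff]
    return flagged, table
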