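"""Synthetic multi-family sequence datasets with planted motifs.

Emulates the statistical structure of a curated family-labeled short-RNA
collection so the whole pipeline can be exercised without any download:
each family is defined by a private set of sequence motifs planted at
random positions in background sequence; family length distributions
overlap by construction, so sequence length alone cannot identify a
family (mirroring the removal of length-predictable classes from real
data). Negative (non-functional) decoys are dinucleotide-preserving
shuffles of real records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabeledDataset, SequenceRecord
from .prep import dinucleotide_shuffle

ALPHABET = "ACGT"

NONFUNCTIONAL_LABEL = "nonfunctional"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated dataset.

    Family length means are drawn uniformly in ``length_mean_range`` with a
    common ``length_spread`` (uniform, +/- spread), truncated to
    ``length_bounds`` — the <= 200 nt regime with overlapping lengths.
    Each family owns ``n_motifs`` random motifs of ``motif_length`` bases;
    each motif is planted in a sequence with probability
    ``insertion_prob`` and each planted base mutated with probability
    ``mutation_rate``. ``background`` is either a length-4 probability
    vector (i.i.d. bases) or a 4x4 stochastic matrix (first-order Markov
    background, useful for stressing shuffle-based rejection).
    """

    n_families: int = 8
    n_per_family: int = 500
    length_mean_range: tuple[int, int] = (60, 160)
    length_spread: int = 30
    length_bounds: tuple[int, int] = (20, 200)
    n_motifs: int = 2
    motif_length: int = 10
    insertion_prob: float = 0.85
    mutation_rate: float = 0.05
    background: tuple | None = None  # None = uniform i.i.d.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_length >= self.length_bounds[0]:
            raise ValueError("motif_length must be shorter than the minimum sequence length")
        for p in (self.insertion_prob, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_families < 1 or self.n_per_family < 1:
            raise ValueError("n_families and n_per_family must be positive")

    @classmethod
    def easy(cls, seed: int = 0, **overrides) -> "SyntheticSpec":
        """Strong-motif preset: every sequence carries its family motifs
        nearly verbatim, so a shallow CNN can learn the families."""
        params = dict(
            n_motifs=6, motif_length=14, insertion_prob=1.0, mutation_rate=0.01, seed=seed
        )
        params.update(overrides)
        return cls(**params)


def _background_sampler(spec: SyntheticSpec, rng: np.random.Generator):
    if spec.background is None:
        probs = np.full(4, 0.25)
        return lambda n: "".join(ALPHABET[i] for i in rng.choice(4, size=n, p=probs))
    bg = np.asarray(spec.background, dtype=float)
    if bg.shape == (4,):
        probs = bg / bg.sum()
        return lambda n: "".join(ALPHABET[i] for i in rng.choice(4, size=n, p=probs))
    if bg.shape == (4, 4):
        trans = bg / bg.sum(axis=1, keepdims=True)
        stationary = np.full(4, 0.25)

        def markov(n: int) -> str:
            if n == 0:
                return ""
            out = [int(rng.choice(4, p=stationary))]
            for _ in range(n - 1):
                out.append(int(rng.choice(4, p=trans[out[-1]])))
            return "".join(ALPHABET[i] for i in out)

        return markov
    raise ValueError("background must be a length-4 vector or a 4x4 matrix")


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return motif
    out = []
    for ch in motif:
        if rng.random() < rate:
            out.append(ALPHABET[int(rng.integers(4))])
        else:
            out.append(ch)
    return "".join(out)


def generate_family_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate the labeled dataset and its ground-truth motif annotations.

    Returns the dataset plus a table with one row per planted motif
    occurrence (columns: id, label, motif_index, motif, start, end).
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sample_background = _background_sampler(spec, rng)
    lo, hi = spec.length_bounds
    records: list[SequenceRecord] = []
    annotations: list[dict] = []
    width = len(str(spec.n_families))
    for fam_idx in range(spec.n_families):
        label = f"FAM{fam_idx + 1:0{width}d}"
        mean = rng.uniform(*spec.length_mean_range)
        motifs = [
            "".join(ALPHABET[int(rng.integers(4))] for _ in range(spec.motif_length))
            for _ in range(spec.n_motifs)
        ]
        for j in range(spec.n_per_family):
            length = int(np.clip(
                round(rng.uniform(mean - spec.length_spread, mean + spec.length_spread)),
                lo,
                hi,
            ))
            seq = list(sample_background(length))
            rec_id = f"{label}_{j:04d}"
            # plant each motif at a random position, avoiding overlaps when
            # space allows (a handful of retries, then overlap is accepted)
            occupied: list[tuple[int, int]] = []
            for m_idx, motif in enumerate(motifs):
                if rng.random() >= spec.insertion_prob:
                    continue
                planted = _mutate(motif, spec.mutation_rate, rng)
                start = None
                for _ in range(20):
                    cand = int(rng.integers(0, length - spec.motif_length + 1))
                    if all(
                        cand + spec.motif_length <= s or cand >= e for s, e in occupied
                    ):
                        start = cand
                        break
                if start is None:
                    start = int(rng.integers(0, length - spec.motif_length + 1))
                occupied.append((start, start + spec.motif_length))
                seq[start : start + spec.motif_length] = list(planted)
                annotations.append(
                    {
                        "id": rec_id,
                        "label": label,
                        "motif_index": m_idx,
                        "motif": motif,
                        "start": start,
                        "end": start + spec.motif_length,
                    }
                )
            records.append(SequenceRecord(rec_id, "".join(seq), label))
    return LabeledDataset(records), pd.DataFrame(
        annotations, columns=["id", "label", "motif_index", "motif", "start", "end"]
    )


def make_negatives(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """One dinucleotide-preserving shuffle per record, labeled non-functional.

    Paired ids are retained with a ``|shuffled`` suffix; combining the
    output with its source doubles the set, one decoy per real sequence.
    """
    if len(dataset) == 0:
        raise ValueError("cannot build negatives from an empty dataset")
    rng = np.random.default_rng(seed)
    out = []
    for rec in dataset:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        shuffled = dinucleotide_shuffle(rec.sequence, seed=sub_seed)
        out.append(SequenceRecord(f"{rec.id}|shuffled", shuffled, NONFUNCTIONAL_LABEL))
    return LabeledDataset(out)
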