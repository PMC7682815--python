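"""Fixed-size channel encodings of DNA/RNA sequences.

Two families of lightweight input representations are provided for the
classifiers in :mod:`rnafam.models`:

* **k-mer one-hot (1D)** — the sequence is cut into consecutive
  non-overlapping k-letter words (k in {1,2,3}); each word becomes a one-hot
  vector over the 4^k canonical words, ordered lexicographically with
  A < C < G < T. A 100-nt sequence at k=2 therefore becomes 50 one-hot
  vectors of 16 entries.
* **space-filling curve (2D)** — the i-th base is written to the i-th cell
  of a Hilbert, Morton or Snake traversal of a square grid sized by
  :func:`grid_side_for`; each cell is a one-hot vector over the 4 DNA
  letters.

Sequences shorter than the fixed input size are padded under one of three
schemes: ``random`` (i.i.d. uniform canonical letters), ``constant`` (one
fixed canonical letter), or ``new`` (a symbol outside the DNA alphabet,
which receives one dedicated extra channel).

The channel axis is always the trailing axis (channels-last).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .curves import curve_path
from .io import SequenceRecord

ALPHABET = "ACGT"
PAD_SYMBOL = "E"

Representation = Literal["kmer", "hilbert", "morton", "snake"]
PaddingScheme = Literal["random", "constant", "new"]

CURVE_REPRESENTATIONS = ("hilbert", "morton", "snake")


@dataclass(frozen=True)
class EncodingSpec:
    """How a sequence becomes a channel array.

    Parameters
    ----------
    representation : {"kmer", "hilbert", "morton", "snake"}
    k : int
        Word length for the k-mer representation; must be 1, 2, or 3.
    max_len : int
        Longest payload the encoding must accommodate (default 200 nt).
    padding : {"random", "constant", "new"}
    constant_symbol : str
        Letter used by the constant scheme (default ``"A"``).
    seed : int
        Seed for the random scheme.
    """

    representation: Representation
    k: int = 1
    max_len: int = 200
    padding: PaddingScheme = "new"
    constant_symbol: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation not in ("kmer",) + CURVE_REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.representation == "kmer" and self.k not in (1, 2, 3):
            raise ValueError(f"k must be in {{1,2,3}}, got {self.k}")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.padding not in ("random", "constant", "new"):
            raise ValueError(f"unknown padding scheme {self.padding!r}")
        if self.constant_symbol not in ALPHABET:
            raise ValueError("constant_symbol must be one of A,C,G,T")


@dataclass
class EncodedBatch:
    """A batched channel encoding.

    ``array`` has shape (n_records, positions, channels) for 1D encodings or
    (n_records, side, side, channels) for 2D encodings. ``payload_lengths``
    counts, per record, the positions carrying original (non-padding) bases.
    """

    array: np.ndarray
    channel_names: list[str]
    payload_lengths: np.ndarray
    spec: EncodingSpec
    ids: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.array.shape[0]

    @property
    def n_channels(self) -> int:
        return self.array.shape[-1]


def grid_side_for(representation: Representation, max_len: int, k: int = 1) -> int:
    """Input dimension for a representation holding ``max_len`` bases.

    Hilbert/Morton use the smallest power-of-two side whose square holds
    the sequence (16 x 16 at 200 nt); Snake uses the ceiling of the square
    root (15 x 15 at 200 nt); the k-mer representation is one-dimensional
    with ceil(max_len / k) positions.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if representation in ("hilbert", "morton"):
        side = 1
        while side * side < max_len:
            side *= 2
        return side
    if representation == "snake":
        return math.isqrt(max_len - 1) + 1
    if representation == "kmer":
        return -(-max_len // k)
    raise ValueError(f"unknown representation {representation!r}")


def pad_sequence(
    sequence: str,
    target_len: int,
    spec: EncodingSpec,
    rng: np.random.Generator | None = None,
) -> str:
    """Extend ``sequence`` to ``target_len`` under the spec's padding scheme.

    The original sequence is an unchanged prefix of the result. The random
    scheme draws i.i.d. uniform canonical letters from ``rng`` (or a fresh
    generator seeded with ``spec.seed``).
    """
    n_pad = target_len - len(sequence)
    if n_pad < 0:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds target length {target_len}"
        )
    if n_pad == 0:
        return sequence
    if spec.padding == "new":
        return sequence + PAD_SYMBOL * n_pad
    if spec.padding == "constant":
        return sequence + spec.constant_symbol * n_pad
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    tail = "".join(rng.choice(list(ALPHABET), size=n_pad))
    return sequence + tail


def kmer_channel_names(k: int, padding: PaddingScheme) -> list[str]:
    """Canonical k-words in lexicographic order, plus one pad channel if 'new'."""
    names = ["".join(w) for w in itertools.product(ALPHABET, repeat=k)]
    if padding == "new":
        names.append(PAD_SYMBOL * k)
    return names


def _word_index(word: str, k: int) -> int:
    # lexicographic base-4 index; any pad symbol sends the word to the
    # dedicated trailing channel
    if PAD_SYMBOL in word:
        return 4**k
    idx = 0
    for ch in word:
        idx = idx * 4 + ALPHABET.index(ch)
    return idx


def _as_sequences(records: Iterable[str | SequenceRecord]) -> tuple[list[str], list[str]]:
    seqs: list[str] = []
    ids: list[str] = []
    for i, r in enumerate(records):
        if isinstance(r, SequenceRecord):
            seqs.append(r.sequence)
            ids.append(r.id)
        else:
            seqs.append(str(r).upper().replace("U", "T"))
            ids.append(str(i))
    return seqs, ids


def encode_kmer(records: Iterable[str | SequenceRecord], spec: EncodingSpec) -> EncodedBatch:
    """Encode sequences as non-overlapping k-mer one-hot vectors (1D).

    Each sequence is padded to ``k * ceil(max_len / k)`` letters, chunked
    into k-words, and each word mapped to its one-hot channel. Words
    containing the 'new' pad symbol map to the single dedicated pad channel.
    """
    if spec.representation != "kmer":
        raise ValueError("spec.representation must be 'kmer'")
    seqs, ids = _as_sequences(records)
    k = spec.k
    n_positions = grid_side_for("kmer", spec.max_len, k)
    target = k * n_positions
    names = kmer_channel_names(k, spec.padding)
    rng = np.random.default_rng(spec.seed)
    array = np.zeros((len(seqs), n_positions, len(names)), dtype=np.float32)
    payload = np.zeros(len(seqs), dtype=np.int64)
    lut = np.full(256, 255, dtype=np.uint8)
    for j, ch in enumerate(ALPHABET):
        lut[ord(ch)] = j
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    rows = np.arange(n_positions)
    for i, seq in enumerate(seqs):
        if len(seq) > spec.max_len:
            raise ValueError(
                f"sequence {ids[i]!r} of length {len(seq)} exceeds max_len {spec.max_len}"
            )
        padded = pad_sequence(seq, target, spec, rng)
        digits = lut[np.frombuffer(padded.encode(), dtype=np.uint8)].reshape(n_positions, k)
        idx = (digits.astype(np.int64) * weights).sum(axis=1)
        idx[(digits == 255).any(axis=1)] = 4**k  # word containing the pad symbol
        array[i, rows, idx] = 1.0
        payload[i] = -(-len(seq) // k)
    return EncodedBatch(array, names, payload, spec, ids)


def encode_curve(records: Iterable[str | SequenceRecord], spec: EncodingSpec) -> EncodedBatch:
    """Fold sequences onto a 2D space-filling-curve grid (one base per cell)."""
    if spec.representation not in CURVE_REPRESENTATIONS:
        raise ValueError("spec.representation must be one of hilbert/morton/snake")
    seqs, ids = _as_sequences(records)
    side = grid_side_for(spec.representation, spec.max_len)
    path = curve_path(spec.representation, side)
    target = side * side
    names = list(ALPHABET) + ([PAD_SYMBOL] if spec.padding == "new" else [])
    symbol_index = {ch: j for j, ch in enumerate(names)}
    if spec.padding != "new":
        symbol_index[spec.constant_symbol] = ALPHABET.index(spec.constant_symbol)
    rng = np.random.default_rng(spec.seed)
    array = np.zeros((len(seqs), side, side, len(names)), dtype=np.float32)
    payload = np.zeros(len(seqs), dtype=np.int64)
    lut = np.zeros(256, dtype=np.int64)
    for ch, j in symbol_index.items():
        lut[ord(ch)] = j
    path_rows = np.array([r for r, _ in path])
    path_cols = np.array([c for _, c in path])
    for i, seq in enumerate(seqs):
        if len(seq) > target:
            raise ValueError(
                f"sequence {ids[i]!r} of length {len(seq)} exceeds grid capacity {target}"
            )
        padded = pad_sequence(seq, target, spec, rng)
        channels = lut[np.frombuffer(padded.encode(), dtype=np.uint8)]
        array[i, path_rows, path_cols, channels] = 1.0
        payload[i] = len(seq)
    return EncodedBatch(array, names, payload, spec, ids)


def encode(records: Iterable[str | SequenceRecord], spec: EncodingSpec) -> EncodedBatch:
    """Dispatch to :func:`encode_kmer` or :func:`encode_curve`."""
    if spec.representation == "kmer":
        return encode_kmer(records, spec)
    return encode_curve(records, spec)


def decode(batch: EncodedBatch) -> list[str]:
    """Recover sequences from an encoded batch, stripping padding.

    For curve encodings the grid is read back along the curve path for
    ``payload_length`` cells, which inverts the encoding exactly. For k-mer
    encodings the payload positions are mapped back to words and the result
    trimmed of trailing padding letters where distinguishable; under the
    'new' scheme a final partial word (k not dividing the length) collapses
    into the pad channel and its bases are not recoverable.
    """
    spec = batch.spec
    out: list[str] = []
    if spec.representation == "kmer":
        for i in range(batch.n_records):
            n = int(batch.payload_lengths[i])
            words = []
            for p in range(n):
                j = int(np.argmax(batch.array[i, p]))
                word = batch.channel_names[j]
                if PAD_SYMBOL in word:
                    word = ""
                words.append(word)
            out.append("".join(words))
        return out
    path = curve_path(spec.representation, grid_side_for(spec.representation, spec.max_len))
    for i in range(batch.n_records):
        n = int(batch.payload_lengths[i])
        letters = []
        for pos in range(n):
            r, c = path[pos]
            letters.append(batch.channel_names[int(np.argmax(batch.array[i, r, c]))])
        out.append("".join(letters))
    return out


class _BaseSequenceEncoder(TransformerMixin, BaseEstimator):
    """Shared sklearn plumbing for the sequence encoders."""

    def fit(self, X=None, y=None):
        spec = self._spec()
        self.spec_ = spec
        self.channel_names_ = (
            kmer_channel_names(spec.k, spec.padding)
            if spec.representation == "kmer"
            else list(ALPHABET) + ([PAD_SYMBOL] if spec.padding == "new" else [])
        )
        return self

    def transform(self, X) -> np.ndarray:
        return self.encode_batch(X).array

    def encode_batch(self, X) -> EncodedBatch:
        if not hasattr(self, "spec_"):
            self.fit()
        return encode(X, self.spec_)


class KmerEncoder(_BaseSequenceEncoder):
    """Transformer producing non-overlapping k-mer one-hot arrays.

    ``transform`` maps an iterable of sequences (strings or
    :class:`~rnafam.io.SequenceRecord`) to a float32 array of shape
    (n, ceil(max_len/k), channels).
    """

    def __init__(self, k=1, max_len=200, padding="new", constant_symbol="A", seed=0):
        self.k = k
        self.max_len = max_len
        self.padding = padding
        self.constant_symbol = constant_symbol
        self.seed = seed

    def _spec(self) -> EncodingSpec:
        return EncodingSpec(
            "kmer", self.k, self.max_len, self.padding, self.constant_symbol, self.seed
        )


class CurveEncoder(_BaseSequenceEncoder):
    """Transformer folding sequences onto a 2D space-filling-curve grid.

    ``transform`` maps sequences to a float32 array of shape
    (n, side, side, channels) with side = :func:`grid_side_for`.
    """

    def __init__(
        self, representation="hilbert", max_len=200, padding="new", constant_symbol="A", seed=0
    ):
        self.representation = representation
        self.max_len = max_len
        self.padding = padding
        self.constant_symbol = constant_symbol
        self.seed = seed

    def _spec(self) -> EncodingSpec:
        return EncodingSpec(
            self.representation, 1, self.max_len, self.padding, self.constant_symbol, self.seed
        )
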