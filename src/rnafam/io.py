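"""Sequence and label input/output.

Reads FASTA files (via Biopython) together with an optional tab-delimited
label table mapping sequence ids to non-coding RNA family names, and applies
the dataset-cleaning filters used throughout the package: removal of records
containing non-canonical letters, removal of over-long records, and removal
of under-represented classes.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

CANONICAL_ALPHABET = frozenset("ACGT")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One identified sequence with an optional family label.

    The sequence is stored uppercase over the DNA alphabet; ``U`` is mapped
    to ``T`` on construction so RNA FASTA files are accepted transparently.
    Non-canonical letters (IUPAC ambiguity codes etc.) are retained here and
    removed later by :func:`filter_canonical`.
    """

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_canonical(self) -> bool:
        return bool(self.sequence) and set(self.sequence) <= CANONICAL_ALPHABET

    def with_label(self, label: Optional[str]) -> "SequenceRecord":
        return SequenceRecord(self.id, self.sequence, label)

    def with_sequence(self, sequence: str) -> "SequenceRecord":
        return SequenceRecord(self.id, sequence, self.label)


@dataclass
class LabeledDataset:
    """An ordered collection of :class:`SequenceRecord` with a class list."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return LabeledDataset(self.records[i])
        return self.records[i]

    @property
    def classes(self) -> list[str]:
        """Sorted unique labels among labeled records."""
        return sorted({r.label for r in self.records if r.label is not None})

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts: collections.Counter[str] = collections.Counter(
            r.label for r in self.records if r.label is not None
        )
        return dict(counts)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    def by_class(self) -> dict[str, list[int]]:
        """Indices of records grouped by label, in input order."""
        groups: dict[str, list[int]] = collections.defaultdict(list)
        for i, r in enumerate(self.records):
            if r.label is not None:
                groups[r.label].append(i)
        return dict(groups)


def _validate_fasta_layout(path: Path) -> None:
    """Cheap structural pre-check so parse errors can name a line."""
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
            elif not seen_header:
                raise FastaParseError(
                    f"{path}: sequence data before any FASTA header at line {lineno}"
                )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-delimited (id, class) table with no header."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: expected two tab-separated columns at line {lineno}")
            table[parts[0]] = parts[1]
    return table


def read_fasta(path: str | Path, label_table: str | Path | None = None) -> LabeledDataset:
    """Read sequences (and optionally labels) into a :class:`LabeledDataset`.

    Records appear in file order, uppercased, with ``U`` mapped to ``T``.
    Records with no entry in the label table are kept unlabeled. Duplicate
    ids are an error; duplicate sequences under distinct ids are retained.
    """
    path = Path(path)
    _validate_fasta_layout(path)
    labels = read_labels(label_table) if label_table is not None else {}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), labels.get(rec.id)))
    return LabeledDataset(records)


def write_fasta(dataset: LabeledDataset | Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in dataset:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_labels(dataset: LabeledDataset | Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in dataset:
            if r.label is not None:
                fh.write(f"{r.id}\t{r.label}\n")


def filter_canonical(
    dataset: LabeledDataset, max_len: int = 200, min_class_size: int = 400
) -> LabeledDataset:
    """Apply the canonical-alphabet, length, and class-size filters.

    Records with any letter outside {A,C,G,T} are removed, then records
    longer than ``max_len``, then whole classes whose surviving count falls
    below ``min_class_size``. Record order is preserved among survivors and
    the operation is idempotent. Unlabeled records are exempt from the
    class-size rule (they belong to no class).
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    if min_class_size < 0:
        raise ValueError("min_class_size must be non-negative")
    survivors = [r for r in dataset if r.is_canonical() and r.length <= max_len]
    counts = collections.Counter(r.label for r in survivors if r.label is not None)
    kept = [
        r
        for r in survivors
        if r.label is None or counts[r.label] >= min_class_size
    ]
    return LabeledDataset(kept)
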