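"""Reading, writing and splitting labeled transcript datasets.

Sequences are normalized at load time to the uppercase DNA alphabet
{A, C, G, T, N}: RNA ``U`` is mapped to ``T`` and any other non-IUPAC-core
character to ``N``.  Labels name the two transcript classes, with non-coding
RNA (``ncRNA``) as the positive class and messenger RNA (``mRNA``) as the
negative class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

POSITIVE_CLASS = "ncRNA"
NEGATIVE_CLASS = "mRNA"
CLASSES = (POSITIVE_CLASS, NEGATIVE_CLASS)

_VALID = set("ACGT")
_NORMALIZE = str.maketrans(
    {c: ("T" if c in "Uu" else c.upper() if c in "acgtACGT" else "N")
     for c in map(chr, range(256))}
)


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T and every non-ACGTU character to N."""
    return seq.translate(_NORMALIZE)


@dataclass(frozen=True)
class SequenceRecord:
    """One transcript: identifier, normalized sequence, optional class label."""

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(
                f"record {self.id!r}: label {self.label!r} not in {CLASSES}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """Ordered collection of records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.label is not None:
                counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    @property
    def labels(self) -> list[str | None]:
        return [rec.label for rec in self.records]

    def with_labels(self, table: dict[str, str]) -> "LabeledDataset":
        """Return a copy with labels attached from an id -> class mapping."""
        missing = [r.id for r in self.records if r.id not in table]
        if missing:
            raise KeyError(f"no label for record(s): {missing[:5]}")
        return LabeledDataset(
            [SequenceRecord(r.id, r.seq, table[r.id]) for r in self.records]
        )


def read_fasta(path: str | Path, label: str | None = None) -> LabeledDataset:
    """Read a FASTA file into a normalized :class:`LabeledDataset`.

    Parameters
    ----------
    path:
        FASTA file (any line wrapping).
    label:
        Optional class attached to every record.
    """
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA header id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, normalize_sequence(str(entry.seq)), label))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return LabeledDataset(records)


def write_fasta(data: LabeledDataset | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    entries = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in data]
    SeqIO.write(entries, str(path), "fasta")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id <TAB> label); a header row is skipped if present."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or not row[0].strip():
                continue
            rid, lab = row[0].strip(), row[1].strip()
            if i == 0 and lab not in CLASSES:
                continue  # header
            if lab not in CLASSES:
                raise ValueError(f"line {i + 1}: unknown label {lab!r}")
            table[rid] = lab
    return table


def write_label_table(data: LabeledDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "label"])
        for rec in data:
            writer.writerow([rec.id, rec.label or ""])


def split_dataset(
    data: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/validation split.

    The training partition holds ``floor(train_fraction * n)`` records
    overall; each class contributes at least ``floor(train_fraction *
    n_class)`` and the rounding remainder goes to the classes with the
    largest fractional parts.  The shuffle is driven solely by ``seed``, so
    identical inputs always produce identical partitions.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must be in (0, 1], got {train_fraction}")
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(data):
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabeled; cannot stratify")
        by_class.setdefault(rec.label, []).append(i)
    if len(by_class) < 2 and train_fraction < 1:
        raise ValueError("both classes must be present for a stratified split")
    classes = sorted(by_class)
    quota = {c: train_fraction * len(by_class[c]) for c in classes}
    n_train_per_class = {c: int(np.floor(quota[c])) for c in classes}
    extras = int(np.floor(train_fraction * len(data))) - sum(n_train_per_class.values())
    for c in sorted(classes, key=lambda c: (-(quota[c] - np.floor(quota[c])), c)):
        if extras <= 0:
            break
        if n_train_per_class[c] < len(by_class[c]):
            n_train_per_class[c] += 1
            extras -= 1
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in classes:
        idx = by_class[cls]
        if len(idx) < 2 and train_fraction < 1:
            raise ValueError(f"class {cls!r} has fewer than 2 records")
        perm = rng.permutation(len(idx))
        n_train = n_train_per_class[cls]
        train_idx.extend(idx[j] for j in perm[:n_train])
        val_idx.extend(idx[j] for j in perm[n_train:])
    train = LabeledDataset([data[i] for i in sorted(train_idx)])
    val = LabeledDataset([data[i] for i in sorted(val_idx)])
    return train, val


def length_summary(data: LabeledDataset) -> dict[str, dict[str, float]]:
    """Per-class length summary: n, median, min, max.

    The median is the standard order statistic (mean of the two middle values
    for even n).
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    lengths: dict[str, list[int]] = {}
    for rec in data:
        lengths.setdefault(rec.label or "unlabeled", []).append(rec.length)
    return {
        cls: {
            "n": len(vals),
            "median": float(np.median(vals)),
            "min": int(min(vals)),
            "max": int(max(vals)),
        }
        for cls, vals in lengths.items()
    }
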