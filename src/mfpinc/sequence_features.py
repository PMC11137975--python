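"""The 91 handcrafted sequence features.

The feature vector concatenates, in fixed order:

* 84 k-mer frequency features for k = 1, 2, 3 (4 + 16 + 64, k-mers in
  lexicographic order over A < C < G < T), each block normalized by the
  number of valid windows;
* five ORF/CDS features — a protein-likeness ``Score``, ``cdsStart``
  (0-based inclusive), ``cdsStop`` (0-based exclusive), ``cdsSize`` and
  ``cdsPercent`` — from a three-frame forward-strand ORF scan;
* total sequence ``length`` and ``GC_content``.

The Score is a documented surrogate for an external CDS scorer: twice the ORF
length in nucleotides, plus 50 if an in-frame stop codon terminates the ORF
and another 50 for a favorable start context (A or G three bases upstream of
the ATG).  Under this scaling, ORFs of 400 nt and above score at least 800,
the conventional strong-protein-evidence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .data_io import LabeledDataset

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

KMER_NAMES: dict[int, list[str]] = {
    k: ["".join(p) for p in product(BASES, repeat=k)] for k in (1, 2, 3)
}
CDS_FEATURE_NAMES = ["Score", "cdsStart", "cdsStop", "cdsSize", "cdsPercent"]
FEATURE_NAMES: list[str] = (
    KMER_NAMES[1] + KMER_NAMES[2] + KMER_NAMES[3]
    + CDS_FEATURE_NAMES + ["length", "GC_content"]
)
N_FEATURES = len(FEATURE_NAMES)  # 91

# The 10-feature preset from combined variance + F-test filtering: GC content,
# Score, cdsStop, cdsSize, and the T, C, GT, GC, ACG, TAT frequencies.
PINC10_PRESET = ["GC_content", "Score", "cdsStop", "cdsSize",
                 "T", "C", "GT", "GC", "ACG", "TAT"]


@dataclass(frozen=True)
class KmerProfile:
    k: int
    frequencies: np.ndarray  # length 4**k, lexicographic order

    @property
    def names(self) -> list[str]:
        return KMER_NAMES[self.k]


@dataclass(frozen=True)
class CdsAnnotation:
    """Longest-ORF annotation; all fields zero when no ORF exists."""

    score: float
    cdsStart: int
    cdsStop: int
    cdsSize: int
    cdsPercent: float


def kmer_frequencies(seq: str, k: int) -> KmerProfile:
    """Normalized k-mer frequencies; windows containing non-ACGT are skipped."""
    if k not in (1, 2, 3):
        raise ValueError(f"k must be in {{1, 2, 3}}, got {k}")
    names = KMER_NAMES[k]
    index = {name: i for i, name in enumerate(names)}
    counts = np.zeros(len(names), dtype=np.float64)
    total = 0
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        pos = index.get(window)
        if pos is not None:
            counts[pos] += 1
            total += 1
    if total:
        counts /= total
    return KmerProfile(k, counts)


def gc_content(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N bases are excluded entirely."""
    gc = sum(seq.count(b) for b in "GC")
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        raise ValueError("sequence has no A/C/G/T base; GC content undefined")
    return gc / acgt


def _orf_candidates(seq: str):
    """Yield (start, stop_exclusive, has_stop) for ATG-anchored ORFs in the
    three forward frames; each ATG runs to its first in-frame stop (stop codon
    included) or, lacking one, to the last complete codon."""
    n = len(seq)
    for frame in range(3):
        starts = []
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in STOP_CODONS:
                for s in starts:
                    yield s, i + 3, True
                starts = []
        # open-ended ORFs: trim to a codon multiple
        for s in starts:
            end = s + ((n - s) // 3) * 3
            if end > s:
                yield s, end, False


def predict_cds(seq: str) -> CdsAnnotation:
    """Scan the three forward frames and annotate the longest ORF.

    Ties on length break toward the smallest start.  Score is
    ``2 * cdsSize``, plus 50 if the ORF is stop-terminated, plus 50 if the
    base three positions upstream of the ATG is A or G.
    """
    if not seq:
        raise ValueError("empty sequence")
    best: tuple[int, int, bool] | None = None
    for start, stop, has_stop in _orf_candidates(seq):
        size = stop - start
        if best is None or size > best[1] - best[0] or (
            size == best[1] - best[0] and start < best[0]
        ):
            best = (start, stop, has_stop)
    if best is None:
        return CdsAnnotation(0.0, 0, 0, 0, 0.0)
    start, stop, has_stop = best
    size = stop - start
    score = 2.0 * size
    if has_stop:
        score += 50.0
    if start >= 3 and seq[start - 3] in "AG":
        score += 50.0
    return CdsAnnotation(score, start, stop, size, size / len(seq))


def extract_sequence_features(seq: str) -> pd.Series:
    """All 91 features for one sequence, indexed by feature name."""
    if not seq:
        raise ValueError("empty sequence")
    values = np.concatenate([kmer_frequencies(seq, k).frequencies for k in (1, 2, 3)])
    cds = predict_cds(seq)
    tail = np.array([
        cds.score, cds.cdsStart, cds.cdsStop, cds.cdsSize, cds.cdsPercent,
        float(len(seq)), gc_content(seq),
    ])
    return pd.Series(np.concatenate([values, tail]), index=FEATURE_NAMES)


def featurize_dataset(data: LabeledDataset) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table (rows = records, 91 named columns) plus the label vector.

    Row order follows the dataset order; the table index is the record id.
    """
    rows = []
    for rec in data:
        try:
            rows.append(extract_sequence_features(rec.seq))
        except ValueError as exc:
            raise ValueError(f"featurization failed for record {rec.id!r}: {exc}") from exc
    table = pd.DataFrame(rows, index=[rec.id for rec in data])
    labels = pd.Series([rec.label for rec in data], index=table.index, name="label")
    return table, labels
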