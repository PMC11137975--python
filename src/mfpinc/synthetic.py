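"""Synthetic transcript generator.

Emulates the statistical structure of the training corpora the pipeline
assumes: balanced classes; coding transcripts with a median length of 1029 nt
carrying a single long ORF embedded between UTRs; non-coding transcripts with
a median length of 321 nt, 90% lncRNA-like and 10% short sncRNA-like, with
long spurious ORFs suppressed.  Lengths are log-normal around the class
median (a log-normal is the simplest strictly-positive family fixed by a
median and a dispersion; the default sigma of 0.5 keeps ~95% of coding
lengths below 2000 nt, matching the concentration of real coding transcripts
in the 0-2000 nt range).

The generator plants exactly the signals the handcrafted features read —
ORF length and coverage, transcript length, and a small GC-content offset
between classes — so every downstream stage is testable without downloads.
It does not emulate plant codon-usage tables, splice structure, or
species composition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import (NEGATIVE_CLASS, POSITIVE_CLASS, LabeledDataset,
                      SequenceRecord)
from .sequence_features import STOP_CODONS, predict_cds

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorParams:
    n_per_class: int = 2000
    coding_length_median: int = 1029
    noncoding_length_median: int = 321
    length_dispersion: float = 0.5
    coding_orf_fraction: float = 0.7
    gc_coding: float = 0.45
    gc_noncoding: float = 0.40
    sncRNA_fraction: float = 0.1
    orf_suppression_nt: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coding_length_median < 30 or self.noncoding_length_median < 30:
            raise ValueError("length medians must be at least 30 nt")
        for name in ("coding_orf_fraction", "sncRNA_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 < self.gc_coding < 1 and 0 < self.gc_noncoding < 1):
            raise ValueError("GC fractions must be in (0, 1)")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_base_probs(gc))) if n else ""


def _lognormal_length(rng: np.random.Generator, median: int, sigma: float,
                      minimum: int) -> int:
    while True:
        n = int(round(rng.lognormal(mean=np.log(median), sigma=sigma)))
        if n >= minimum:
            return n


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    # rejection-sample non-stop codons so the ORF never self-terminates
    while True:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOP_CODONS:
            return codon


def generate_coding(params: GeneratorParams) -> LabeledDataset:
    """mRNA-like records: one planted ORF covering ``coding_orf_fraction`` of
    the transcript, flanked by UTR sequence at the coding GC composition."""
    rng = np.random.default_rng(params.seed)
    records = []
    for i in range(params.n_per_class):
        length = _lognormal_length(rng, params.coding_length_median,
                                   params.length_dispersion, minimum=33)
        orf_len = max(9, int(params.coding_orf_fraction * length) // 3 * 3)
        n_inner = orf_len // 3 - 2
        orf = "ATG" + "".join(_random_codon(rng, params.gc_coding)
                              for _ in range(n_inner))
        orf += str(rng.choice(sorted(STOP_CODONS)))
        utr = length - orf_len
        start = int(rng.integers(0, utr + 1))
        seq = (_random_bases(rng, start, params.gc_coding) + orf
               + _random_bases(rng, utr - start, params.gc_coding))
        records.append(SequenceRecord(f"mrna_{i:05d}", seq, NEGATIVE_CLASS))
    return LabeledDataset(records)


def _suppress_orfs(seq: str, max_nt: int) -> str:
    """Replace a mid-ORF codon with TAA until no ORF exceeds ``max_nt``."""
    chars = list(seq)
    for _ in range(100):  # generous bound; each pass shortens the longest ORF
        ann = predict_cds("".join(chars))
        if ann.cdsSize <= max_nt:
            break
        mid = ann.cdsStart + (ann.cdsSize // 2 // 3) * 3
        chars[mid:mid + 3] = "TAA"
    return "".join(chars)


def generate_noncoding(params: GeneratorParams) -> LabeledDataset:
    """ncRNA-like records: lncRNA-like log-normal lengths with an
    ``sncRNA_fraction`` share of short (60-200 nt) records; spurious ORFs
    longer than the suppression threshold are disrupted with stop codons."""
    rng = np.random.default_rng(params.seed + 1)
    records = []
    for i in range(params.n_per_class):
        if rng.random() < params.sncRNA_fraction:
            length = int(rng.integers(60, 201))
            prefix = "sncrna"
        else:
            length = _lognormal_length(rng, params.noncoding_length_median,
                                       params.length_dispersion, minimum=30)
            prefix = "lncrna"
        seq = _suppress_orfs(_random_bases(rng, length, params.gc_noncoding),
                             params.orf_suppression_nt)
        records.append(SequenceRecord(f"{prefix}_{i:05d}", seq, POSITIVE_CLASS))
    return LabeledDataset(records)


def generate_dataset(params: GeneratorParams) -> LabeledDataset:
    """Balanced, deterministically shuffled dataset of both classes."""
    pos = generate_noncoding(params).records
    neg = generate_coding(params).records
    combined = pos + neg
    rng = np.random.default_rng(params.seed + 2)
    order = rng.permutation(len(combined))
    return LabeledDataset([combined[j] for j in order])


def default_params(n_per_class: int = 2000, seed: int = 0, **overrides) -> GeneratorParams:
    return replace(GeneratorParams(), n_per_class=n_per_class, seed=seed, **overrides)
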