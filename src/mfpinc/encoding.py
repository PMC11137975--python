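"""Fixed-length numeric encodings of transcripts.

Two encodings feed the deep-feature extractor: a four-dimensional one-hot
matrix (columns ordered A, C, G, T) and an integer index vector for a learned
nucleotide embedding (0 = padding, 1..4 = A, C, G, T, 5 = N).  Sequences
longer than the target length are truncated at the 3' end, keeping the 5'
prefix; shorter sequences are padded at the tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAD_INDEX = 0
N_INDEX = 5
VOCAB_SIZE = 6  # pad, A, C, G, T, N
BASE_ORDER = "ACGT"
_INDEX_OF = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}


@dataclass(frozen=True)
class OneHotMatrix:
    """L x 4 binary matrix; rows beyond ``effective_length`` are all-zero."""

    values: np.ndarray
    effective_length: int


@dataclass(frozen=True)
class IndexVector:
    """Length-L integer vector over {0..5}; trailing pad entries are 0."""

    values: np.ndarray
    effective_length: int


def _check(seq: str, length: int) -> None:
    if length <= 0:
        raise ValueError(f"target length must be positive, got {length}")
    if not seq:
        raise ValueError("empty sequence cannot be encoded")


def encode_onehot(seq: str, length: int) -> OneHotMatrix:
    """One-hot encode the 5' prefix of ``seq`` into an L x 4 matrix.

    ``N`` bases and padding rows are all-zero.
    """
    _check(seq, length)
    eff = min(len(seq), length)
    mat = np.zeros((length, 4), dtype=np.float64)
    for i, base in enumerate(seq[:eff]):
        col = BASE_ORDER.find(base)
        if col >= 0:
            mat[i, col] = 1.0
    return OneHotMatrix(mat, eff)


def encode_indices(seq: str, length: int) -> IndexVector:
    """Map the 5' prefix of ``seq`` to embedding indices, tail-padded with 0."""
    _check(seq, length)
    eff = min(len(seq), length)
    vec = np.zeros(length, dtype=np.int64)
    for i, base in enumerate(seq[:eff]):
        vec[i] = _INDEX_OF.get(base, N_INDEX)
    return IndexVector(vec, eff)


def encode_indices_batch(seqs: list[str], length: int) -> np.ndarray:
    """Stack :func:`encode_indices` over sequences into an (n, L) array."""
    return np.stack([encode_indices(s, length).values for s in seqs]) if seqs \
        else np.zeros((0, length), dtype=np.int64)
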