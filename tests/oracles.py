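"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration or textbook formulas,
sharing no code with the package implementation.
"""

from __future__ import annotations

import math

STOPS = {"TAA", "TAG", "TGA"}


def bruteforce_longest_orf(seq: str):
    """Enumerate every ATG -> stop pairing in all three frames, plus
    stop-less ATG-to-end spans, and return (start, stop, size, has_stop) for
    the longest (ties: smallest start); None if no ORF exists."""
    candidates = []
    n = len(seq)
    for start in range(n - 2):
        if seq[start:start + 3] != "ATG":
            continue
        stop_found = None
        for j in range(start + 3, n - 2, 3):
            if seq[j:j + 3] in STOPS:
                stop_found = j + 3
                break
        if stop_found is not None:
            candidates.append((start, stop_found, True))
        else:
            end = start + ((n - start) // 3) * 3
            if end > start:
                candidates.append((start, end, False))
    if not candidates:
        return None
    best = max(candidates, key=lambda c: (c[1] - c[0], -c[0]))
    return best[0], best[1], best[1] - best[0], best[2]


def hand_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Textbook confusion-matrix metrics, None where the denominator is 0."""

    def div(a, b):
        return None if b == 0 else a / b

    mcc_den = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return {
        "acc": (tp + tn) / (tp + tn + fp + fn),
        "mcc": None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
        "se": div(tp, tp + fn),
        "spc": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
        "f1": div(2 * tp, 2 * tp + fp + fn),
    }


def mann_whitney_auc(labels01, scores) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), by direct enumeration."""
    pos = [s for y, s in zip(labels01, scores) if y == 1]
    neg = [s for y, s in zip(labels01, scores) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
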