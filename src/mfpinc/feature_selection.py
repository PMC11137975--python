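"""Feature selection: variance-above-mean filtering and the combined
variance + F-test pathway that reduces the 91 handcrafted features to 10.

The variance filter keeps columns whose sample variance (n - 1 denominator)
strictly exceeds the mean of all column variances.  The F statistic is the
two-class one-way ANOVA F (between-group over within-group mean square); the
combined pathway first applies the variance filter and then keeps the top-k
survivors ranked by F, breaking ties by the fixed column order.  Selections
are meant to be fitted on training rows only and re-applied to other
partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SelectionResult:
    method: str  # variance_above_mean | f_test_topk | pinc_combined
    selected_names: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    fitted_on_n: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "selected_names": self.selected_names,
            "scores": {k: (None if not np.isfinite(v) else v)
                       for k, v in self.scores.items()},
            "fitted_on_n": self.fitted_on_n,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        scores = {k: (np.inf if v is None else v)
                  for k, v in payload["scores"].items()}
        return cls(payload["method"], payload["selected_names"], scores,
                   payload["fitted_on_n"])


def variance_above_mean(table: pd.DataFrame) -> SelectionResult:
    """Keep columns whose sample variance strictly exceeds the mean variance."""
    if len(table) < 2:
        raise ValueError("variance filtering needs at least 2 rows")
    variances = table.var(axis=0, ddof=1)
    threshold = variances.mean()
    keep = [name for name in table.columns if variances[name] > threshold]
    return SelectionResult(
        "variance_above_mean", keep,
        {name: float(variances[name]) for name in table.columns}, len(table),
    )


def f_test_scores(table: pd.DataFrame, labels: pd.Series | np.ndarray) -> dict[str, float]:
    """Per-feature one-way ANOVA F statistic for the two-class labels.

    A feature with zero within-class variance but a between-class difference
    maps to +inf; a globally constant feature maps to 0.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(classes)}")
    masks = [y == c for c in classes]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each class needs at least 2 rows")
    X = table.to_numpy(dtype=np.float64)
    n = len(y)
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for m in masks:
        grp = X[m]
        ss_between += len(grp) * (grp.mean(axis=0) - grand) ** 2
        ss_within += ((grp - grp.mean(axis=0)) ** 2).sum(axis=0)
    ms_between = ss_between / (len(classes) - 1)
    ms_within = ss_within / (n - len(classes))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f[(ms_within == 0) & (ms_between > 0)] = np.inf
    f[(ms_within == 0) & (ms_between == 0)] = 0.0
    return {name: float(f[i]) for i, name in enumerate(table.columns)}


def select_pinc10(
    table: pd.DataFrame, labels: pd.Series | np.ndarray, k: int = 10
) -> SelectionResult:
    """Variance-above-mean filtering followed by top-k F-statistic ranking."""
    survivors = variance_above_mean(table).selected_names
    if len(survivors) < k:
        raise ValueError(
            f"only {len(survivors)} features survive variance filtering; need {k}"
        )
    scores = f_test_scores(table[survivors], labels)
    order = {name: i for i, name in enumerate(table.columns)}
    ranked = sorted(survivors, key=lambda name: (-scores[name], order[name]))
    return SelectionResult("pinc_combined", ranked[:k],
                           {name: scores[name] for name in survivors}, len(table))


def apply_selection(table: pd.DataFrame, selection: SelectionResult) -> pd.DataFrame:
    """Restrict and reorder columns to ``selection.selected_names``."""
    missing = [n for n in selection.selected_names if n not in table.columns]
    if missing:
        raise KeyError(f"selected column(s) missing from table: {missing}")
    return table[selection.selected_names]
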