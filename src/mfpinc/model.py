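"""Feature fusion and the final classifiers; end-to-end pipeline orchestration.

The fused representation is the column-wise concatenation of the 91
handcrafted features with the 1200 deep features (handcrafted block first,
1291 columns by default), z-score standardized with parameters fitted on the
training partition only.  Three classifier families are supported: the
primary random forest (500 trees, seeded), an RBF-kernel SVM, and Gaussian
naive Bayes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .data_io import (POSITIVE_CLASS, LabeledDataset, read_fasta,
                      read_label_table, split_dataset)
from .deep_features import (ExtractorConfig, GruExtractor, build_extractor,
                            train_extractor)
from .encoding import encode_indices_batch
from .evaluation import EvaluationReport, evaluate_predictions
from .feature_selection import SelectionResult, apply_selection
from .sequence_features import featurize_dataset
from .synthetic import GeneratorParams, generate_dataset

logger = logging.getLogger("mfpinc")

CLASSIFIER_KINDS = ("rfc", "svm", "nb")


@dataclass
class FusedFeatureTable:
    """Standardized fused feature matrix with its training-fitted scaler."""

    values: pd.DataFrame
    scaler_mean: pd.Series
    scaler_scale: pd.Series

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)


def fuse_features(
    seq_table: pd.DataFrame,
    deep_table: pd.DataFrame,
    scaler: tuple[pd.Series, pd.Series] | None = None,
) -> FusedFeatureTable:
    """Concatenate handcrafted and deep feature blocks and standardize.

    With ``scaler=None`` the rows are treated as the training partition and
    the per-column mean/scale are fitted on them; pass a previously fitted
    ``(mean, scale)`` pair to transform validation or test rows.
    """
    if len(seq_table) != len(deep_table):
        raise ValueError(
            f"row count mismatch: {len(seq_table)} handcrafted vs {len(deep_table)} deep"
        )
    deep_table = deep_table.set_axis(seq_table.index)
    fused = pd.concat([seq_table, deep_table], axis=1)
    if scaler is None:
        mean = fused.mean(axis=0)
        scale = fused.std(axis=0, ddof=0).replace(0.0, 1.0)
    else:
        mean, scale = scaler
    standardized = (fused - mean) / scale
    return FusedFeatureTable(standardized, mean, scale)


@dataclass
class ClassifierBundle:
    kind: str
    fitted_model: object
    column_names: list[str]
    seed: int
    threshold: float = 0.5
    selection: SelectionResult | None = None
    extractor_fingerprint: str | None = None
    scaler_mean: pd.Series | None = None
    scaler_scale: pd.Series | None = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.fitted_model, directory / "classifier.joblib")
        meta = {
            "kind": self.kind,
            "column_names": self.column_names,
            "seed": self.seed,
            "threshold": self.threshold,
            "extractor_fingerprint": self.extractor_fingerprint,
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=1))
        if self.scaler_mean is not None:
            pd.DataFrame({"mean": self.scaler_mean, "scale": self.scaler_scale}) \
                .to_csv(directory / "scaler.csv")
        if self.selection is not None:
            self.selection.to_json(directory / "selection.json")

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        model = joblib.load(directory / "classifier.joblib")
        scaler_mean = scaler_scale = None
        if (directory / "scaler.csv").exists():
            scaler = pd.read_csv(directory / "scaler.csv", index_col=0)
            scaler_mean, scaler_scale = scaler["mean"], scaler["scale"]
        selection = None
        if (directory / "selection.json").exists():
            selection = SelectionResult.from_json(directory / "selection.json")
        return cls(meta["kind"], model, meta["column_names"], meta["seed"],
                   meta["threshold"], selection, meta["extractor_fingerprint"],
                   scaler_mean, scaler_scale)


def _make_model(kind: str, seed: int):
    if kind == "rfc":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if kind == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if kind == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")


def train_classifier(
    table: FusedFeatureTable | pd.DataFrame,
    labels,
    kind: str = "rfc",
    seed: int = 0,
    threshold: float = 0.5,
) -> ClassifierBundle:
    """Fit the requested classifier family on a (fused) feature table."""
    X = table.values if isinstance(table, FusedFeatureTable) else table
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < 10:
        raise ValueError(f"need at least 10 rows to train, got {len(y)}")
    model = _make_model(kind, seed)
    model.fit(X.to_numpy(), y)
    bundle = ClassifierBundle(kind, model, list(X.columns), seed, threshold)
    if isinstance(table, FusedFeatureTable):
        bundle.scaler_mean = table.scaler_mean
        bundle.scaler_scale = table.scaler_scale
    return bundle


def predict(bundle: ClassifierBundle, table: FusedFeatureTable | pd.DataFrame):
    """Per-row (probability of ncRNA, hard label); probability >= threshold
    maps to ncRNA."""
    X = table.values if isinstance(table, FusedFeatureTable) else table
    missing = [c for c in bundle.column_names if c not in X.columns]
    extra = [c for c in X.columns if c not in bundle.column_names]
    if missing or extra:
        raise ValueError(f"schema mismatch: missing={missing[:5]} extra={extra[:5]}")
    if len(X) == 0:
        return np.zeros(0), np.array([], dtype=object)
    X = X[bundle.column_names]
    pos = list(bundle.fitted_model.classes_).index(POSITIVE_CLASS)
    probs = bundle.fitted_model.predict_proba(X.to_numpy())[:, pos]
    labels = np.where(probs >= bundle.threshold, POSITIVE_CLASS, "mRNA")
    return probs, labels


@dataclass
class PipelineConfig:
    """Everything the training pipeline needs: a data source, a split, the
    extractor hyperparameters, and the classifier family."""

    fasta_pos: str | None = None
    fasta_neg: str | None = None
    fasta: str | None = None
    label_table: str | None = None
    synthetic: GeneratorParams | None = None
    train_fraction: float = 0.7
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    classifier: str = "rfc"
    selection: SelectionResult | None = None
    seed: int = 0
    out_dir: str | None = None


@dataclass
class PipelineResult:
    bundle: ClassifierBundle
    extractor: GruExtractor
    report: EvaluationReport
    history: list[dict]
    seq_train: pd.DataFrame
    seq_val: pd.DataFrame
    deep_train: pd.DataFrame
    deep_val: pd.DataFrame
    y_train: pd.Series
    y_val: pd.Series
    fused_train: FusedFeatureTable
    fused_val: FusedFeatureTable


def _load_dataset(config: PipelineConfig) -> LabeledDataset:
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    if config.fasta_pos and config.fasta_neg:
        pos = read_fasta(config.fasta_pos, label=POSITIVE_CLASS)
        neg = read_fasta(config.fasta_neg, label="mRNA")
        return LabeledDataset(pos.records + neg.records)
    if config.fasta and config.label_table:
        data = read_fasta(config.fasta)
        return data.with_labels(read_label_table(config.label_table))
    raise ValueError(
        "pipeline config must name synthetic parameters, a positive/negative "
        "FASTA pair, or a FASTA plus a label table"
    )


def run_training_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read -> split -> featurize -> train extractor -> extract -> fuse ->
    fit classifier -> evaluate on the validation partition."""
    stages: list[tuple[str, float]] = []

    def stage(name: str):
        t = time.perf_counter()
        stages.append((name, t))
        logger.info("stage %-22s start", name)

    stage("load")
    data = _load_dataset(config)
    stage("split")
    train, val = split_dataset(data, config.train_fraction, config.seed)
    stage("handcrafted_features")
    seq_train, y_train = featurize_dataset(train)
    seq_val, y_val = featurize_dataset(val)
    if config.selection is not None:
        seq_train = apply_selection(seq_train, config.selection)
        seq_val = apply_selection(seq_val, config.selection)
    stage("encode")
    L = config.extractor.seq_length
    idx_train = encode_indices_batch([r.seq for r in train], L)
    idx_val = encode_indices_batch([r.seq for r in val], L)
    stage("train_extractor")
    extractor = build_extractor(config.extractor)
    _, history = train_extractor(extractor, idx_train, y_train.to_numpy())
    stage("deep_features")
    deep_train = _extract_chunked(extractor, idx_train)
    deep_val = _extract_chunked(extractor, idx_val)
    stage("fuse")
    fused_train = fuse_features(seq_train, deep_train)
    fused_val = fuse_features(seq_val, deep_val,
                              scaler=(fused_train.scaler_mean, fused_train.scaler_scale))
    stage("classifier")
    bundle = train_classifier(fused_train, y_train.to_numpy(),
                              kind=config.classifier, seed=config.seed)
    bundle.extractor_fingerprint = extractor.config.fingerprint
    bundle.selection = config.selection
    stage("evaluate")
    probs, labels = predict(bundle, fused_val)
    report = evaluate_predictions(y_val.to_numpy(), labels, probs)
    for (name, t0), (_, t1) in zip(stages, stages[1:]):
        logger.info("stage %-22s %6.2fs", name, t1 - t0)
    result = PipelineResult(bundle, extractor, report, history,
                            seq_train, seq_val, deep_train, deep_val,
                            y_train, y_val, fused_train, fused_val)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.save(out)
        extractor.save(out / "extractor.npz")
        report.to_json(out / "validation_report.json")
    return result


def _extract_chunked(extractor: GruExtractor, idx: np.ndarray,
                     chunk: int = 64) -> pd.DataFrame:
    from .deep_features import extract_deep_features_batch

    parts = [extract_deep_features_batch(extractor, idx[i:i + chunk])
             for i in range(0, len(idx), chunk)]
    if not parts:
        return extract_deep_features_batch(extractor, idx)
    return pd.concat(parts, ignore_index=True)


def fusion_ablation(result: PipelineResult, seed: int = 0) -> dict[str, float]:
    """Validation accuracy of the fused table against each single source."""
    out: dict[str, float] = {}
    y_tr, y_val = result.y_train.to_numpy(), result.y_val.to_numpy()
    probs, labels = predict(result.bundle, result.fused_val)
    out["fused"] = evaluate_predictions(y_val, labels).acc
    for name, (tr, va) in {
        "handcrafted": (result.seq_train, result.seq_val),
        "deep": (result.deep_train, result.deep_val),
    }.items():
        fused_tr = fuse_features(tr, tr.iloc[:, :0])
        fused_va = fuse_features(va, va.iloc[:, :0],
                                 scaler=(fused_tr.scaler_mean, fused_tr.scaler_scale))
        b = train_classifier(fused_tr, y_tr, kind=result.bundle.kind, seed=seed)
        _, labels = predict(b, fused_va)
        out[name] = evaluate_predictions(y_val, labels).acc
    return out
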