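"""Evaluation protocols: metric suite, stratified CV, family holdout, paired tests.

Three protocols mirror how transfection-efficiency classifiers are compared:

* a fixed stratified train/val/test split for the binary benchmark,
* stratified 5-fold cross-validation for the multiclass task, identical
  folds and seeds across embedding methods,
* lipid-family holdout — every family (defined by tail/zwitterion counts)
  serves once as the test set, probing generalization to unseen chemotypes.

Because the datasets are imbalanced, the metric suite reports one-vs-rest
AUC, balanced accuracy, support-weighted F1, and the Matthews correlation
coefficient.  AUC is marked absent for a fold whose true labels contain
fewer than two distinct classes (the family-holdout exclusion rule).
Method pairs are compared with paired one-sided t-tests across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .chem_io import LipidRecord
from .classify import GBTConfig, MULTICLASS_DEFAULT, predict_proba, train_classifier
from .featurize import EmbeddingMatrix


@dataclass
class MetricSet:
    """One fold's metrics; ``auc`` is None exactly when undefined."""

    auc: float | None
    balanced_accuracy: float
    weighted_f1: float
    mcc: float


@dataclass
class EvalReport:
    """Per-fold metrics per method, aggregates, and paired-test p-values."""

    per_fold: dict[str, list[tuple[str, MetricSet]]] = field(default_factory=dict)
    comparisons: list[tuple[tuple[str, str], str, float]] = field(default_factory=list)

    METRICS = ("auc", "balanced_accuracy", "weighted_f1", "mcc")

    def aggregate(self) -> dict[str, MetricSet]:
        """Unweighted fold means, computed only over folds where defined."""
        out = {}
        for method, folds in self.per_fold.items():
            vals = {}
            for m in self.METRICS:
                xs = [getattr(ms, m) for _, ms in folds if getattr(ms, m) is not None]
                vals[m] = float(np.mean(xs)) if xs else None
            out[method] = MetricSet(**vals)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_fold": {
                m: [{"fold": f, **asdict(ms)} for f, ms in folds]
                for m, folds in self.per_fold.items()
            },
            "aggregate": {m: asdict(ms) for m, ms in self.aggregate().items()},
            "comparisons": [
                {"method_a": a, "method_b": b, "metric": metric, "p_value": p}
                for (a, b), metric, p in self.comparisons
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"method": m, "fold": f, "metric": metric, "value": getattr(ms, metric)}
            for m, folds in self.per_fold.items()
            for f, ms in folds
            for metric in self.METRICS
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def metric_suite(
    y_true: Sequence[int],
    p_pred: np.ndarray,
    classes: Sequence[int] | None = None,
    *,
    tol: float = 1e-6,
) -> MetricSet:
    """AUC / balanced accuracy / weighted F1 / MCC for one evaluation fold.

    ``p_pred`` columns follow ``classes`` (default ``0..M-1``).  Multiclass
    AUC is one-vs-rest, macro-averaged over the classes for which it is
    defined (present with both positives and negatives); it is reported
    absent when the fold's true labels hold fewer than two distinct classes.
    """
    y_true = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    if p.ndim != 2 or p.shape[0] != len(y_true):
        raise ValueError("p_pred must be an (n, M) probability matrix aligned with y_true")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
        raise ValueError("probability rows must sum to 1")
    classes = np.asarray(classes if classes is not None else np.arange(p.shape[1]), dtype=int)
    if len(classes) != p.shape[1]:
        raise ValueError("classes must match probability columns")

    y_pred = classes[p.argmax(axis=1)]
    present = np.unique(y_true)

    auc: float | None = None
    if len(present) >= 2:
        if len(classes) == 2:
            auc = float(roc_auc_score(y_true == classes[1], p[:, 1]))
        else:
            per_class = [
                float(roc_auc_score(y_true == c, p[:, j]))
                for j, c in enumerate(classes)
                if 0 < np.sum(y_true == c) < len(y_true)
            ]
            auc = float(np.mean(per_class)) if per_class else None

    import warnings

    with warnings.catch_warnings():
        # single-class folds are expected under family holdout
        warnings.simplefilter("ignore", UserWarning)
        return MetricSet(
            auc=auc,
            balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
            weighted_f1=float(
                f1_score(y_true, y_pred, average="weighted", zero_division=0)
            ),
            mcc=float(matthews_corrcoef(y_true, y_pred)),
        )


def stratified_kfold(
    labels: Sequence[int], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Index arrays of k disjoint, class-stratified test folds.

    Folds partition the index set; per-fold class counts deviate from exact
    proportionality by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # classes thinner than k
        return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def stratified_split(
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test index split (default 80/10/10)."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    f_train, f_val, f_test = fractions
    rest, test = train_test_split(
        idx, test_size=f_test, stratify=labels, random_state=seed
    )
    train, val = train_test_split(
        rest, test_size=f_val / (f_train + f_val), stratify=labels[rest],
        random_state=seed,
    )
    return train, val, test


def _labels_of(records: Sequence[LipidRecord], kind: str) -> np.ndarray:
    attr = {"binary": "binary_label", "multiclass": "multiclass_label"}[kind]
    vals = [getattr(r, attr) for r in records]
    if any(v is None for v in vals):
        raise ValueError(f"records lack {attr}; derive labels first")
    return np.asarray(vals, dtype=int)


def crossval_experiment(
    records: Sequence[LipidRecord],
    embeddings: Mapping[str, EmbeddingMatrix],
    k: int = 5,
    seed: int = 0,
    config: GBTConfig | None = None,
    *,
    label_kind: str = "multiclass",
    compare: bool = True,
) -> EvalReport:
    """Stratified k-fold CV of every embedding method with shared folds/seeds.

    Each method trains one classifier per fold on the other k-1 folds with
    identical hyperparameters, then is scored on the held-out fold.  With
    ``compare``, all ordered method pairs get paired one-sided t-tests per
    metric (alternative: first method's fold metrics are greater).
    """
    config = config or MULTICLASS_DEFAULT
    y = _labels_of(records, label_kind)
    ids = [r.id for r in records]
    aligned = {m: e.subset(ids) for m, e in embeddings.items()}
    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(len(records))

    report = EvalReport()
    for method, emb in aligned.items():
        fold_metrics = []
        for fold_no, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = train_classifier(emb.values[train_idx], y[train_idx], config)
            p = predict_proba(model, emb.values[test_idx])
            fold_metrics.append(
                (str(fold_no), metric_suite(y[test_idx], p, classes=model.classes))
            )
        report.per_fold[method] = fold_metrics

    if compare and len(aligned) >= 2:
        methods = list(aligned)
        for i, a in enumerate(methods):
            for b in methods[i + 1:]:
                for metric in EvalReport.METRICS:
                    xs = [getattr(ms, metric) for _, ms in report.per_fold[a]]
                    ys = [getattr(ms, metric) for _, ms in report.per_fold[b]]
                    if any(v is None for v in xs + ys):
                        continue
                    report.comparisons.append(
                        ((a, b), metric, paired_one_sided_ttest(xs, ys))
                    )
    return report


def family_holdout_experiment(
    records: Sequence[LipidRecord],
    embeddings: Mapping[str, EmbeddingMatrix],
    config: GBTConfig | None = None,
    *,
    label_kind: str = "multiclass",
) -> EvalReport:
    """Leave-one-family-out evaluation (one run per lipid family).

    Train and test families are disjoint by construction.  A family whose
    test labels contain fewer than two distinct classes keeps its other
    metrics but has AUC marked absent — families with no satisfying lipids
    cannot be ranked.
    """
    config = config or MULTICLASS_DEFAULT
    families = [r.family for r in records]
    if any(f is None for f in families):
        raise ValueError("records lack family ids")
    families = np.asarray(families, dtype=int)
    unique_fams = np.unique(families)
    if len(unique_fams) < 2:
        raise ValueError("family holdout requires at least 2 families")
    y = _labels_of(records, label_kind)
    ids = [r.id for r in records]
    aligned = {m: e.subset(ids) for m, e in embeddings.items()}

    report = EvalReport()
    for method, emb in aligned.items():
        fold_metrics = []
        for fam in unique_fams:
            test_mask = families == fam
            model = train_classifier(emb.values[~test_mask], y[~test_mask], config)
            p = predict_proba(model, emb.values[test_mask])
            fold_metrics.append(
                (f"family_{fam}", metric_suite(y[test_mask], p, classes=model.classes))
            )
        report.per_fold[method] = fold_metrics
    return report


def paired_one_sided_ttest(
    metric_a: Sequence[float], metric_b: Sequence[float]
) -> float:
    """p-value for the alternative mean(a - b) > 0, paired across folds.

    With zero-variance differences the t statistic is undefined: an exactly
    positive constant difference is reported below the machine floor, a zero
    or negative one as p = 1.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("inputs must be equal-length vectors of >= 2 fold metrics")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return float(np.nextafter(0, 1)) if diff.mean() > 0 else 1.0
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.pvalue)
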