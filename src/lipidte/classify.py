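"""Gradient-boosted decision-tree heads over molecular embeddings.

A single boosted-tree interface serves every embedding method; the classifier
sees nothing but the ionizable-lipid embedding matrix.  The multiclass task
uses a frozen configuration (depth 5, learning rate 0.005, 5000 iterations);
the binary task selects its configuration by grid search on a validation
split.  LightGBM is the backend; any gradient-boosting library honouring the
``GBTConfig`` contract could be substituted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

import lightgbm as lgb

from .featurize import EmbeddingMatrix
from .gcn import DegenerateLabelsError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GBTConfig:
    """Boosted-tree hyperparameters; defaults are the frozen multiclass setup."""

    depth: int = 5
    learning_rate: float = 0.005
    iterations: int = 5000
    loss: str = "multiclass"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("binary", "multiclass"):
            raise ValueError(f"loss must be 'binary' or 'multiclass', got {self.loss!r}")
        if self.learning_rate <= 0 or self.iterations < 1 or self.depth < 1:
            raise ValueError("invalid GBT hyperparameters")


#: the fixed multiclass configuration (small-dataset regime, no tuning)
MULTICLASS_DEFAULT = GBTConfig(depth=5, learning_rate=0.005, iterations=5000,
                               loss="multiclass")

#: default grid for the binary task (axes unpublished; conventional lattice)
BINARY_GRID: tuple[GBTConfig, ...] = tuple(
    GBTConfig(depth=d, learning_rate=lr, iterations=it, loss="binary")
    for d in (4, 5, 6) for lr in (0.005, 0.01, 0.05) for it in (1000, 5000)
)


@dataclass
class ClassifierModel:
    backend: "lgb.LGBMClassifier"
    config: GBTConfig
    classes: tuple[int, ...]
    feature_dim: int


def _as_matrix(x: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, EmbeddingMatrix) else np.asarray(x, dtype=float)


def train_classifier(
    x: EmbeddingMatrix | np.ndarray,
    y: Sequence[int],
    config: GBTConfig | None = None,
) -> ClassifierModel:
    """Fit a boosted-tree classifier; deterministic given ``config.seed``."""
    config = config or MULTICLASS_DEFAULT
    values = _as_matrix(x)
    y = np.asarray(y, dtype=int)
    if values.shape[0] != len(y):
        raise ValueError(f"{values.shape[0]} embedding rows vs {len(y)} labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    thin = classes[counts < 2]
    if thin.size:
        logger.warning("classes with <2 training members: %s", thin.tolist())
    backend = lgb.LGBMClassifier(
        max_depth=config.depth,
        num_leaves=2 ** config.depth,
        learning_rate=config.learning_rate,
        n_estimators=config.iterations,
        objective="binary" if config.loss == "binary" else "multiclass",
        random_state=config.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        min_child_samples=5,
        verbosity=-1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        backend.fit(values, y)
    return ClassifierModel(
        backend=backend,
        config=config,
        classes=tuple(int(c) for c in backend.classes_),
        feature_dim=values.shape[1],
    )


def predict_proba(model: ClassifierModel, x: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Class-probability matrix (rows sum to 1, columns follow ``model.classes``)."""
    values = _as_matrix(x)
    if values.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dim {values.shape[1]} does not match model dim {model.feature_dim}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        p = model.backend.predict_proba(values)
    return p / p.sum(axis=1, keepdims=True)


def grid_search(
    train: tuple[EmbeddingMatrix | np.ndarray, Sequence[int]],
    val: tuple[EmbeddingMatrix | np.ndarray, Sequence[int]],
    grid: Sequence[GBTConfig] = BINARY_GRID,
    *,
    metric: str = "auc",
    seed: int = 0,
) -> GBTConfig:
    """Pick the grid point maximizing a validation metric (default AUC).

    Ties are broken toward the simpler model: fewer iterations, then
    smaller depth, then smaller learning rate.
    """
    from .evaluate import metric_suite  # local import to avoid a cycle

    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    x_val, y_val = val
    results = []
    for cfg in grid:
        cfg = replace(cfg, seed=seed)
        model = train_classifier(train[0], train[1], cfg)
        ms = metric_suite(np.asarray(y_val, dtype=int), predict_proba(model, x_val),
                         classes=model.classes)
        score = getattr(ms, metric if metric != "auc" else "auc")
        if score is None:
            score = -np.inf
        results.append((cfg, float(score)))
    best_score = max(s for _, s in results)
    contenders = [c for c, s in results if s == best_score]
    contenders.sort(key=lambda c: (c.iterations, c.depth, c.learning_rate))
    return contenders[0]
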