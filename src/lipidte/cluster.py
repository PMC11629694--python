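"""Embedding-space structure: K-means, NMI against labels, 2-D projection.

Answers whether an embedding organizes the lipid library the same way the
chemists do (families by tail/zwitterion count) or the assay does (TE
class): K-means partitions the embedding, normalized mutual information
quantifies agreement with a reference labelling, and a 2-D projection makes
the geometry inspectable.  PCA is the built-in deterministic projector; any
external callable (e.g. a UMAP backend) can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import normalized_mutual_info_score

from .featurize import EmbeddingMatrix


@dataclass
class ClusterAssignment:
    ids: tuple[str, ...]
    labels: np.ndarray
    k: int
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels must align")
        if len(np.unique(self.labels)) > self.k:
            raise ValueError("more distinct labels than clusters")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "cluster": self.labels}).to_csv(path, index=False)


def kmeans_cluster(
    x: EmbeddingMatrix, k: int, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """Best-of-``n_init`` K-means by inertia; deterministic given ``seed``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.n:
        raise ValueError(f"k={k} exceeds number of points n={x.n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x.values)
    return ClusterAssignment(
        ids=x.ids, labels=labels, k=k, inertia=float(km.inertia_), seed=seed
    )


def normalized_mutual_info(
    a: Sequence[int], b: Sequence[int], *, average: str = "arithmetic"
) -> float:
    """NMI between two partitions, in [0, 1].

    Normalizer is the arithmetic mean of the two entropies by default
    (``average='geometric'`` for the alternative).  A single-cluster
    partition has zero entropy and yields NMI 0 by convention — including
    when both partitions are constant, where some conventions return 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-D sequences")
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method=average))


def nmi_summary(
    assignment: ClusterAssignment, references: dict[str, Sequence[int]]
) -> dict[str, float]:
    """NMI of a clustering against each reference labelling (family, TE, ...)."""
    return {
        name: normalized_mutual_info(assignment.labels, ref)
        for name, ref in references.items()
    }


def project_2d(
    x: EmbeddingMatrix,
    method: str = "pca",
    seed: int = 0,
    projector: Callable[[np.ndarray, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Deterministic n x 2 layout of the embedding.

    ``method='pca'`` uses the built-in exact PCA; ``method='external'``
    delegates to ``projector(values, seed)`` (e.g. a UMAP wrapper).
    """
    if x.n < 3:
        raise ValueError("need at least 3 points to project")
    if x.dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if method == "pca":
        return PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(
            x.values
        )
    if method == "external":
        if projector is None:
            raise ValueError("method 'external' requires a projector callable")
        out = np.asarray(projector(x.values, seed), dtype=float)
        if out.shape != (x.n, 2):
            raise ValueError(f"projector returned shape {out.shape}, expected ({x.n}, 2)")
        return out
    raise ValueError(f"unknown projection method {method!r}")
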