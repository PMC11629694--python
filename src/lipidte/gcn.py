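"""Degree-binned graph convolutional embedder for ionizable lipids.

The model maps a hydrogen-suppressed atom graph to a fixed-length embedding:

1. symmetric-normalized propagation ``P = D̃^(-1/2) (A + I) D̃^(-1/2)``
   (self-loops included in the degree matrix D̃),
2. per-layer convolutions ``H^l = ReLU(P H^(l-1) W_i^l)`` where the weight
   matrix ``W_i^l`` applied to a node's row is selected by that node's degree
   bin ``i = clamp(degree, 1, n_degree_bins)`` — one weight matrix per
   possible neighbor count, default five per layer,
3. sum pooling over nodes, a dense layer to a 32-dimensional molecule
   embedding, and a linear-softmax classification head trained with
   cross-entropy; the head is discarded once embeddings are extracted.

Dropout (default 0.3) is applied to convolution outputs during training
only.  Training is full-batch Adam with early stopping on validation loss
(best-epoch weights restored), fully reproducible given the config seed.

All graphs in a batch are packed into one block-diagonal sparse propagation
matrix, so an epoch is a handful of sparse/dense matrix products; gradients
are derived by hand (the model is a few chained linear maps and ReLUs).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .featurize import EmbeddingMatrix, MolGraph, NODE_FEATURE_DIM


class DegenerateLabelsError(ValueError):
    """Training labels contain fewer than two classes."""


@dataclass(frozen=True)
class GCNConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference setup: two convolutional layers, five
    degree-binned weight matrices per layer, a 32-dim dense embedding,
    dropout 0.3, up to 5000 epochs with early-stopping patience 500.  The
    convolution hidden width and the optimizer (full-batch Adam, lr 1e-3)
    are unpublished details and are therefore plain configuration.
    """

    n_conv_layers: int = 2
    hidden_dim: int = 64
    embed_dim: int = 32
    n_degree_bins: int = 5
    dropout: float = 0.3
    max_epochs: int = 5000
    patience: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    n_classes: int = 2
    in_dim: int = NODE_FEATURE_DIM

    def __post_init__(self) -> None:
        if self.n_degree_bins < 1:
            raise ValueError("n_degree_bins must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class GCNModel:
    """Learned weights: per-(layer, degree-bin) conv matrices, dense embedding
    layer, and the softmax head used only during training."""

    conv_weights: list[np.ndarray]  # layer l -> (n_degree_bins, d_in, d_out)
    dense_w: np.ndarray             # (hidden, embed_dim)
    dense_b: np.ndarray             # (embed_dim,)
    head_w: np.ndarray              # (embed_dim, n_classes)
    head_b: np.ndarray              # (n_classes,)
    config: GCNConfig

    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_weights, self.dense_w, self.dense_b, self.head_w, self.head_b]

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config JSON + all weight arrays."""
        arrays = {f"conv_{l}": w for l, w in enumerate(self.conv_weights)}
        arrays |= {
            "dense_w": self.dense_w, "dense_b": self.dense_b,
            "head_w": self.head_w, "head_b": self.head_b,
        }
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GCNModel":
        with np.load(path, allow_pickle=False) as data:
            config = GCNConfig(**json.loads(str(data["config"])))
            conv = [data[f"conv_{l}"] for l in range(config.n_conv_layers)]
            return cls(
                conv_weights=conv,
                dense_w=data["dense_w"], dense_b=data["dense_b"],
                head_w=data["head_w"], head_b=data["head_b"],
                config=config,
            )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def init_gcn(config: GCNConfig) -> GCNModel:
    """Glorot-style seeded initialization."""
    rng = np.random.default_rng(config.seed)

    def glorot(d_in, d_out):
        s = np.sqrt(6.0 / (d_in + d_out))
        return rng.uniform(-s, s, size=(d_in, d_out))

    conv = []
    d_in = config.in_dim
    for _ in range(config.n_conv_layers):
        conv.append(np.stack([glorot(d_in, config.hidden_dim)
                              for _ in range(config.n_degree_bins)]))
        d_in = config.hidden_dim
    return GCNModel(
        conv_weights=conv,
        dense_w=glorot(config.hidden_dim, config.embed_dim),
        dense_b=np.zeros(config.embed_dim),
        head_w=glorot(config.embed_dim, config.n_classes),
        head_b=np.zeros(config.n_classes),
        config=config,
    )


# ---------------------------------------------------------------------------
# forward primitives
# ---------------------------------------------------------------------------

def normalized_propagation(graph: MolGraph) -> np.ndarray:
    """Symmetric-normalized propagation matrix with self-loops.

    ``Â = A + I`` and ``D̃ = diag(rowsum(Â))``; returns
    ``D̃^(-1/2) Â D̃^(-1/2)``, symmetric with entries in [0, 1].
    """
    a_hat = graph.adjacency.astype(float) + np.eye(graph.n_nodes)
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def degree_bins(graph: MolGraph, n_bins: int) -> np.ndarray:
    """Per-node weight-matrix selector: clamp(degree, 1, n_bins), 0-indexed."""
    return np.clip(graph.degrees, 1, n_bins) - 1


def _apply_bins(z: np.ndarray, weights: np.ndarray, bins: np.ndarray) -> np.ndarray:
    out = np.empty((z.shape[0], weights.shape[2]))
    for i in range(weights.shape[0]):
        rows = bins == i
        if rows.any():
            out[rows] = z[rows] @ weights[i]
    return out


def gcn_layer_forward(
    h_prev: np.ndarray,
    graph: MolGraph,
    layer_weights: np.ndarray,
    *,
    training: bool = False,
    dropout: float = 0.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One degree-binned convolution: row v is
    ``ReLU([P @ h_prev @ W_bin(v)]_v)``; inverted dropout when training."""
    if h_prev.shape[0] != graph.n_nodes:
        raise ValueError(f"h_prev has {h_prev.shape[0]} rows for {graph.n_nodes} nodes")
    if h_prev.shape[1] != layer_weights.shape[1]:
        raise ValueError(
            f"feature dim {h_prev.shape[1]} vs weight input dim {layer_weights.shape[1]}"
        )
    bins = degree_bins(graph, layer_weights.shape[0])
    h = np.maximum(_apply_bins(normalized_propagation(graph) @ h_prev, layer_weights, bins), 0.0)
    if training and dropout > 0.0:
        rng = rng if rng is not None else np.random.default_rng()
        h = h * (rng.random(h.shape) >= dropout) / (1.0 - dropout)
    return h


def gcn_forward(
    graph: MolGraph,
    model: GCNModel,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full pass for one graph: (32-dim embedding, class logits).

    Sum pooling over the final convolution makes the output invariant to
    node order.
    """
    h = graph.node_features
    for w in model.conv_weights:
        h = gcn_layer_forward(
            h, graph, w, training=training, dropout=model.config.dropout, rng=rng
        )
    pooled = h.sum(axis=0)
    embedding = pooled @ model.dense_w + model.dense_b
    logits = embedding @ model.head_w + model.head_b
    return embedding, logits


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(
    y_true: np.ndarray, p_pred: np.ndarray, *, eps: float = 1e-12, tol: float = 1e-6
) -> float:
    """Mean categorical cross-entropy ``-Σ_c y_c log p_c`` over observations.

    ``y_true`` is one-hot (or an index vector); predictions are clipped to
    ``[eps, 1]`` before the log; rows of ``p_pred`` must sum to 1 within
    ``tol``.
    """
    p = np.atleast_2d(np.asarray(p_pred, dtype=float))
    if np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
        raise ValueError("prediction rows must sum to 1")
    y = np.asarray(y_true)
    if y.ndim == p.ndim - 1 or (p.shape[0] > 1 and y.ndim == 1):
        onehot = np.zeros_like(p)
        onehot[np.arange(p.shape[0]), y.astype(int)] = 1.0
        y = onehot
    y = np.atleast_2d(y)
    return float(-(y * np.log(np.clip(p, eps, 1.0))).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# batched training
# ---------------------------------------------------------------------------

class _Batch:
    """All graphs packed into one block-diagonal sparse system."""

    def __init__(self, graphs: Sequence[MolGraph], n_bins: int):
        self.x = np.concatenate([g.node_features for g in graphs])
        self.prop = sp.block_diag(
            [sp.csr_matrix(normalized_propagation(g)) for g in graphs], format="csr"
        )
        self.bins = np.concatenate([degree_bins(g, n_bins) for g in graphs])
        sizes = [g.n_nodes for g in graphs]
        col = np.arange(sum(sizes))
        row = np.repeat(np.arange(len(graphs)), sizes)
        self.pool = sp.csr_matrix(
            (np.ones(len(col)), (row, col)), shape=(len(graphs), sum(sizes))
        )
        self.n_graphs = len(graphs)


def _batch_forward(model: GCNModel, batch: _Batch, *, training: bool,
                   rng: np.random.Generator | None):
    cfg = model.config
    cache = {"z": [], "a": [], "mask": [], "h_in": []}
    h = batch.x
    for w in model.conv_weights:
        cache["h_in"].append(h)
        z = batch.prop @ h
        a = _apply_bins(z, w, batch.bins)
        h = np.maximum(a, 0.0)
        if training and cfg.dropout > 0.0:
            mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h = h * mask
        else:
            mask = None
        cache["z"].append(z)
        cache["a"].append(a)
        cache["mask"].append(mask)
    pooled = batch.pool @ h
    emb = pooled @ model.dense_w + model.dense_b
    logits = emb @ model.head_w + model.head_b
    probs = _softmax(logits)
    cache |= {"h_out": h, "pooled": pooled, "emb": emb, "probs": probs}
    return cache


def _batch_backward(model: GCNModel, batch: _Batch, cache: dict, y_onehot: np.ndarray):
    cfg = model.config
    n = batch.n_graphs
    d_logits = (cache["probs"] - y_onehot) / n
    grads = {
        "head_w": cache["emb"].T @ d_logits,
        "head_b": d_logits.sum(axis=0),
    }
    d_emb = d_logits @ model.head_w.T
    grads["dense_w"] = cache["pooled"].T @ d_emb
    grads["dense_b"] = d_emb.sum(axis=0)
    d_pooled = d_emb @ model.dense_w.T
    d_h = batch.pool.T @ d_pooled
    conv_grads: list[np.ndarray] = [None] * cfg.n_conv_layers
    for l in range(cfg.n_conv_layers - 1, -1, -1):
        if cache["mask"][l] is not None:
            d_h = d_h * cache["mask"][l]
        d_a = d_h * (cache["a"][l] > 0)
        w = model.conv_weights[l]
        g = np.zeros_like(w)
        d_z = np.empty_like(cache["z"][l])
        for i in range(w.shape[0]):
            rows = batch.bins == i
            if rows.any():
                g[i] = cache["z"][l][rows].T @ d_a[rows]
                d_z[rows] = d_a[rows] @ w[i].T
            else:
                d_z[rows] = 0.0
        conv_grads[l] = g
        if l > 0:
            d_h = batch.prop.T @ d_z  # prop is symmetric
    grads["conv"] = conv_grads
    return grads


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train_gcn(
    train_graphs: Sequence[MolGraph],
    train_labels: Sequence[int],
    val_graphs: Sequence[MolGraph],
    val_labels: Sequence[int],
    config: GCNConfig | None = None,
) -> tuple[GCNModel, TrainHistory]:
    """Train the embedder with cross-entropy; early-stop on validation loss.

    Stops once validation loss has not improved for ``config.patience``
    epochs (or at ``max_epochs``) and restores the best-epoch weights; ties
    keep the earliest epoch.  Deterministic given ``config.seed``.
    """
    config = config or GCNConfig()
    y_train = np.asarray(train_labels, dtype=int)
    y_val = np.asarray(val_labels, dtype=int)
    if len(train_graphs) == 0 or len(val_graphs) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if len(np.unique(y_train)) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    if y_train.max() >= config.n_classes or y_val.max() >= config.n_classes:
        raise ValueError("labels must be in 0..n_classes-1")

    rng = np.random.default_rng(config.seed + 1)
    model = init_gcn(config)
    train_batch = _Batch(train_graphs, config.n_degree_bins)
    val_batch = _Batch(val_graphs, config.n_degree_bins)
    y_tr_onehot = np.eye(config.n_classes)[y_train]
    y_va_onehot = np.eye(config.n_classes)[y_val]

    opt = _Adam(model.parameters(), config.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_params = [p.copy() for p in model.parameters()]

    for epoch in range(1, config.max_epochs + 1):
        cache = _batch_forward(model, train_batch, training=True, rng=rng)
        train_loss = cross_entropy_loss(y_tr_onehot, cache["probs"])
        grads = _batch_backward(model, train_batch, cache, y_tr_onehot)
        flat = [*grads["conv"], grads["dense_w"], grads["dense_b"],
                grads["head_w"], grads["head_b"]]
        opt.step(model.parameters(), flat)

        val_cache = _batch_forward(model, val_batch, training=False, rng=None)
        val_loss = cross_entropy_loss(y_va_onehot, val_cache["probs"])
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)

        if val_loss < best_val:  # strict: ties keep the earliest epoch
            best_val = val_loss
            history.best_epoch = epoch
            best_params = [p.copy() for p in model.parameters()]
        if epoch - history.best_epoch >= config.patience:
            break
    history.stopped_epoch = epoch

    restored = copy.deepcopy(model)
    for p, best in zip(restored.parameters(), best_params):
        p[...] = best
    return restored, history


def extract_embeddings(
    model: GCNModel, graphs: Sequence[MolGraph], ids: Sequence[str]
) -> EmbeddingMatrix:
    """Evaluation-mode embeddings (no dropout) for downstream classifiers."""
    if len(graphs) != len(ids):
        raise ValueError("graphs and ids must align")
    batch = _Batch(graphs, model.config.n_degree_bins)
    cache = _batch_forward(model, batch, training=False, rng=None)
    return EmbeddingMatrix(ids=tuple(ids), values=cache["emb"], method="gcn")
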