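"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (loops, explicit enumeration, closed
forms) and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from rdkit import Chem


# ---------------------------------------------------------------------------
# circular-fingerprint environment enumeration
# ---------------------------------------------------------------------------

def bfs_distances(mol: Chem.Mol, start: int) -> dict[int, int]:
    adj: dict[int, list[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].append(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].append(b.GetBeginAtomIdx())
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def total_environment_count(smiles: str, radius: int) -> int:
    """Sum over atoms of the number of realizable radii (0..radius), where
    radius r >= 1 is realizable iff some atom sits at exactly distance r."""
    mol = Chem.MolFromSmiles(smiles)
    total = 0
    for atom in mol.GetAtoms():
        dist = bfs_distances(mol, atom.GetIdx())
        reached = set(dist.values())
        total += sum(1 for r in range(radius + 1) if r == 0 or r in reached)
    return total


def distinct_environment_counts(smiles: str, radius: int) -> Counter:
    """Multiset of circular environments keyed by canonical rooted fragment
    SMILES (exact for acyclic molecules)."""
    mol = Chem.MolFromSmiles(smiles)
    out: Counter = Counter()
    for atom in mol.GetAtoms():
        dist = bfs_distances(mol, atom.GetIdx())
        reached = set(dist.values())
        for r in range(radius + 1):
            if r > 0 and r not in reached:
                continue
            atoms = [i for i, d in dist.items() if d <= r]
            # mark the center with a map number so the canonical (unrooted)
            # fragment SMILES is a sound rooted-environment key
            atom.SetAtomMapNum(1)
            raw = Chem.MolFragmentToSmiles(
                mol, atomsToUse=atoms, canonical=False, allHsExplicit=True
            )
            atom.SetAtomMapNum(0)
            # canonicalize the fragment as a molecule of its own (the parent's
            # atom ranking would otherwise leak into the string)
            frag = Chem.MolToSmiles(Chem.MolFromSmiles(raw, sanitize=False))
            out[(r, frag)] += 1
    return out


# ---------------------------------------------------------------------------
# naive GCN forward pass
# ---------------------------------------------------------------------------

def naive_gcn_forward(graph, model):
    """Per-node, per-neighbor message passing with explicit loops."""
    n = graph.n_nodes
    adj = graph.adjacency
    deg_hat = adj.sum(axis=1) + 1  # self-loop degrees
    h = graph.node_features.copy()
    n_bins = model.config.n_degree_bins
    for w in model.conv_weights:
        msg = np.zeros((n, h.shape[1]))
        for v in range(n):
            msg[v] += h[v] / deg_hat[v]  # self message
            for u in range(n):
                if adj[v, u]:
                    msg[v] += h[u] / math.sqrt(deg_hat[v] * deg_hat[u])
        out = np.zeros((n, w.shape[2]))
        for v in range(n):
            bin_v = min(max(int(adj[v].sum()), 1), n_bins) - 1
            out[v] = np.maximum(msg[v] @ w[bin_v], 0.0)
        h = out
    pooled = np.zeros(h.shape[1])
    for v in range(n):
        pooled += h[v]
    emb = pooled @ model.dense_w + model.dense_b
    logits = emb @ model.head_w + model.head_b
    return emb, logits


# ---------------------------------------------------------------------------
# confusion-matrix metric suite
# ---------------------------------------------------------------------------

def confusion_matrix_metrics(y_true, y_pred, classes):
    """Balanced accuracy, weighted F1, multiclass MCC from an explicit
    confusion matrix."""
    classes = list(classes)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1

    recalls = []
    f1s, supports = [], []
    for i in range(k):
        support = cm[i].sum()
        if support == 0:
            continue
        tp = cm[i, i]
        recalls.append(tp / support)
        pred_pos = cm[:, i].sum()
        prec = tp / pred_pos if pred_pos else 0.0
        rec = tp / support
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        supports.append(support)
    bal_acc = float(np.mean(recalls))
    weighted_f1 = float(np.average(f1s, weights=supports))

    # generalized (correlation-of-confusion-matrix) MCC
    t_k = cm.sum(axis=1)
    p_k = cm.sum(axis=0)
    c = np.trace(cm)
    s = cm.sum()
    num = c * s - t_k @ p_k
    den = math.sqrt((s * s - p_k @ p_k) * (s * s - t_k @ t_k))
    mcc = 0.0 if den == 0 else float(num / den)
    return bal_acc, weighted_f1, mcc


def mann_whitney_auc(y_bin, scores):
    """AUC as the normalized Mann-Whitney U count with tie correction."""
    pos = [s for y, s in zip(y_bin, scores) if y]
    neg = [s for y, s in zip(y_bin, scores) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def ovr_macro_auc(y_true, p, classes):
    """One-vs-rest macro AUC over classes with positives and negatives."""
    per_class = []
    for j, c in enumerate(classes):
        y_bin = [int(t == c) for t in y_true]
        if 0 < sum(y_bin) < len(y_bin):
            per_class.append(mann_whitney_auc(y_bin, p[:, j]))
    return float(np.mean(per_class)) if per_class else None


# ---------------------------------------------------------------------------
# contingency-table NMI
# ---------------------------------------------------------------------------

def contingency_nmi(a, b, average="arithmetic"):
    n = len(a)
    table = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    mi = 0.0
    for (x, y), c in table.items():
        p_xy = c / n
        mi += p_xy * math.log(p_xy * n * n / (pa[x] * pb[y]))
    ha = -sum((c / n) * math.log(c / n) for c in pa.values())
    hb = -sum((c / n) * math.log(c / n) for c in pb.values())
    if ha == 0.0 or hb == 0.0:
        return 0.0
    norm = 0.5 * (ha + hb) if average == "arithmetic" else math.sqrt(ha * hb)
    return max(0.0, mi) / norm
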