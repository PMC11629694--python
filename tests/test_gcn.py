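import numpy as np
import pytest

import lipidte as lt
from conftest import random_molgraph
from lipidte.featurize import MolGraph, NODE_FEATURE_DIM
from lipidte.gcn import (
    DegenerateLabelsError,
    GCNConfig,
    degree_bins,
    extract_embeddings,
    init_gcn,
    train_gcn,
)
from oracles import naive_gcn_forward


def permuted_graph(graph: MolGraph, perm: np.ndarray) -> MolGraph:
    return MolGraph(
        node_features=graph.node_features[perm],
        adjacency=graph.adjacency[np.ix_(perm, perm)],
        degrees=graph.degrees[perm],
        atom_symbols=tuple(graph.atom_symbols[i] for i in perm),
    )


def toy_task():
    """Linear alkanes labelled by a chain-length threshold; separable by a
    logistic fit on atom counts, hence learnable from sum-pooled features."""
    ns = list(range(2, 42))
    graphs = [lt.build_mol_graph("C" * n) for n in ns]
    labels = [int(n >= 22) for n in ns]
    tr = [i for i in range(40) if i % 4 != 3]
    va = [i for i in range(40) if i % 4 == 3]
    return graphs, labels, tr, va


class TestPropagation:
    def test_single_node_is_identity(self):
        g = lt.build_mol_graph("C")
        assert np.array_equal(lt.normalized_propagation(g), [[1.0]])

    def test_two_node_path(self):
        g = lt.build_mol_graph("CC")
        assert np.allclose(lt.normalized_propagation(g), [[0.5, 0.5], [0.5, 0.5]])

    def test_random_graphs_vs_entrywise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_molgraph(rng, n_max=8)
            p = lt.normalized_propagation(g)
            a_hat = g.adjacency + np.eye(g.n_nodes)
            d_hat = a_hat.sum(axis=1)
            expected = np.array(
                [
                    [a_hat[u, v] / np.sqrt(d_hat[u] * d_hat[v])
                     for v in range(g.n_nodes)]
                    for u in range(g.n_nodes)
                ]
            )
            assert np.allclose(p, expected, atol=1e-12)
            assert np.allclose(p, p.T) and p.min() >= 0 and p.max() <= 1


class TestForward:
    def test_layer_matches_per_node_message_oracle(self):
        rng = np.random.default_rng(1)
        cfg = GCNConfig(hidden_dim=8, seed=1)
        model = init_gcn(cfg)
        for _ in range(10):
            g = random_molgraph(rng, n_max=6)
            out = lt.gcn_layer_forward(g.node_features, g, model.conv_weights[0])
            # naive: normalized self+neighbor sum, then the node's bin matrix
            a_hat = g.adjacency + np.eye(g.n_nodes)
            d_hat = a_hat.sum(axis=1)
            for v in range(g.n_nodes):
                msg = sum(
                    a_hat[v, u] / np.sqrt(d_hat[v] * d_hat[u]) * g.node_features[u]
                    for u in range(g.n_nodes)
                )
                b = min(max(g.degrees[v], 1), cfg.n_degree_bins) - 1
                assert np.allclose(out[v], np.maximum(msg @ model.conv_weights[0][b], 0),
                                   atol=1e-6)

    def test_full_forward_vs_naive_oracle_50_graphs(self):
        rng = np.random.default_rng(2)
        model = init_gcn(GCNConfig(hidden_dim=12, seed=2, n_classes=3))
        for _ in range(50):
            g = random_molgraph(rng, n_max=8)
            emb, logits = lt.gcn_forward(g, model)
            emb_o, logits_o = naive_gcn_forward(g, model)
            assert np.allclose(emb, emb_o, atol=1e-6)
            assert np.allclose(logits, logits_o, atol=1e-6)

    def test_embedding_dim_default_32(self):
        model = init_gcn(GCNConfig())
        g = lt.build_mol_graph("CCCCCC(=O)OCCN(C)C")
        emb, logits = lt.gcn_forward(g, model)
        assert emb.shape == (32,) and logits.shape == (2,)

    def test_permutation_invariance_of_pooled_embedding(self):
        rng = np.random.default_rng(3)
        model = init_gcn(GCNConfig(hidden_dim=8, seed=3))
        for _ in range(5):
            g = random_molgraph(rng, n_max=8)
            emb, _ = lt.gcn_forward(g, model)
            for _ in range(20):
                perm = rng.permutation(g.n_nodes)
                emb_p, _ = lt.gcn_forward(permuted_graph(g, perm), model)
                assert np.allclose(emb, emb_p, atol=1e-8)

    def test_zero_features_give_bias_image(self):
        model = init_gcn(GCNConfig(hidden_dim=8, seed=4))
        g = lt.build_mol_graph("CCO")
        g.node_features = np.zeros_like(g.node_features)
        emb, logits = lt.gcn_forward(g, model)
        assert np.allclose(emb, model.dense_b)
        assert np.allclose(logits, model.dense_b @ model.head_w + model.head_b)

    def test_degree_bins_clamped_and_covered(self):
        battery = ["CC", "CCC", "CC(C)C", "CC(C)(C)C", "FP(F)(F)(F)F"]
        seen = set()
        for smi in battery:
            seen.update(degree_bins(lt.build_mol_graph(smi), 5).tolist())
        assert seen == {0, 1, 2, 3, 4}
        # degree-6 center clamps to the top bin
        g6 = lt.build_mol_graph("F[S](F)(F)(F)(F)F")
        assert degree_bins(g6, 5).max() == 4

    def test_shape_mismatch_rejected(self):
        model = init_gcn(GCNConfig())
        g = lt.build_mol_graph("CC")
        with pytest.raises(ValueError):
            lt.gcn_layer_forward(np.zeros((2, 10)), g, model.conv_weights[0])


class TestCrossEntropy:
    @pytest.mark.parametrize(
        "y, p, expected",
        [
            ((1, 0), (0.5, 0.5), np.log(2)),
            ((1, 0), (1.0, 0.0), 0.0),
            ((0, 1), (0.2, 0.8), -np.log(0.8)),
        ],
    )
    def test_worked_examples(self, y, p, expected):
        assert lt.cross_entropy_loss(np.array([y]), np.array([p])) == pytest.approx(
            expected, abs=1e-4
        )

    def test_batch_is_mean(self):
        y = np.array([[1, 0], [0, 1]])
        p = np.array([[0.5, 0.5], [0.2, 0.8]])
        expected = (np.log(2) - np.log(0.8)) / 2
        assert lt.cross_entropy_loss(y, p) == pytest.approx(expected)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            lt.cross_entropy_loss(np.array([[1, 0]]), np.array([[0.7, 0.7]]))


class TestTraining:
    def test_seeded_determinism_bitwise(self):
        graphs, labels, tr, va = toy_task()
        cfg = GCNConfig(hidden_dim=8, max_epochs=40, patience=40, seed=7)
        runs = [
            train_gcn([graphs[i] for i in tr], [labels[i] for i in tr],
                      [graphs[i] for i in va], [labels[i] for i in va], cfg)
            for _ in range(2)
        ]
        assert runs[0][1].train_loss == runs[1][1].train_loss
        assert runs[0][1].val_loss == runs[1][1].val_loss
        for w1, w2 in zip(runs[0][0].parameters(), runs[1][0].parameters()):
            assert np.array_equal(w1, w2)

    def test_separable_toy_task_learned(self):
        graphs, labels, tr, va = toy_task()
        cfg = GCNConfig(hidden_dim=16, max_epochs=1500, patience=300,
                        learning_rate=0.01, dropout=0.1, seed=0)
        model, hist = train_gcn(
            [graphs[i] for i in tr], [labels[i] for i in tr],
            [graphs[i] for i in va], [labels[i] for i in va], cfg,
        )
        assert min(hist.train_loss) < 0.1
        assert min(hist.val_loss) < hist.val_loss[0]  # loss decreases
        assert hist.stopped_epoch <= cfg.max_epochs
        assert hist.best_epoch <= hist.stopped_epoch

    def test_early_stopping_respects_patience(self):
        graphs, labels, tr, va = toy_task()
        cfg = GCNConfig(hidden_dim=4, max_epochs=500, patience=20,
                        learning_rate=1e-5, seed=0)  # barely moves: stops early
        _, hist = train_gcn(
            [graphs[i] for i in tr], [labels[i] for i in tr],
            [graphs[i] for i in va], [labels[i] for i in va], cfg,
        )
        assert hist.stopped_epoch - hist.best_epoch >= cfg.patience \
            or hist.stopped_epoch == cfg.max_epochs

    def test_single_class_training_rejected(self):
        graphs, _, tr, va = toy_task()
        with pytest.raises(DegenerateLabelsError):
            train_gcn([graphs[i] for i in tr], [0] * len(tr),
                      [graphs[i] for i in va], [0] * len(va), GCNConfig())

    def test_gradients_match_finite_differences(self):
        """Hand-derived backprop agrees with numerical differentiation."""
        from lipidte.gcn import _Batch, _batch_backward, _batch_forward, cross_entropy_loss

        rng = np.random.default_rng(5)
        cfg = GCNConfig(hidden_dim=5, embed_dim=4, n_classes=2, dropout=0.0, seed=5)
        model = init_gcn(cfg)
        graphs = [random_molgraph(rng, n_max=5) for _ in range(4)]
        batch = _Batch(graphs, cfg.n_degree_bins)
        y = np.eye(2)[[0, 1, 0, 1]]

        cache = _batch_forward(model, batch, training=False, rng=None)
        grads = _batch_backward(model, batch, cache, y)
        flat = [*grads["conv"], grads["dense_w"], grads["dense_b"],
                grads["head_w"], grads["head_b"]]

        eps = 1e-6
        for param, grad in zip(model.parameters(), flat):
            it = np.ndindex(*param.shape)
            for idx in list(it)[:: max(1, param.size // 10)]:  # spot-check entries
                orig = param[idx]
                param[idx] = orig + eps
                up = cross_entropy_loss(
                    y, _batch_forward(model, batch, training=False, rng=None)["probs"]
                )
                param[idx] = orig - eps
                down = cross_entropy_loss(
                    y, _batch_forward(model, batch, training=False, rng=None)["probs"]
                )
                param[idx] = orig
                assert grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestEmbeddings:
    def test_extraction_shape_and_determinism(self):
        graphs, labels, tr, va = toy_task()
        cfg = GCNConfig(hidden_dim=8, max_epochs=30, patience=30, seed=0)
        model, _ = train_gcn(
            [graphs[i] for i in tr], [labels[i] for i in tr],
            [graphs[i] for i in va], [labels[i] for i in va], cfg,
        )
        ids = [str(i) for i in range(len(graphs))]
        emb1 = extract_embeddings(model, graphs, ids)
        emb2 = extract_embeddings(model, graphs, ids)
        assert emb1.values.shape == (len(graphs), 32) and emb1.method == "gcn"
        assert np.array_equal(emb1.values, emb2.values)  # eval mode, no dropout
        # duplicated graphs map to identical rows
        dup = extract_embeddings(model, [graphs[0], graphs[0]], ["a", "b"])
        assert np.array_equal(dup.values[0], dup.values[1])

    def test_checkpoint_roundtrip(self, tmp_path):
        model = init_gcn(GCNConfig(hidden_dim=8, seed=9))
        p = tmp_path / "ckpt.npz"
        model.save(p)
        back = lt.GCNModel.load(p)
        assert back.config == model.config
        for a, b in zip(model.parameters(), back.parameters()):
            assert np.array_equal(a, b)
        g = lt.build_mol_graph("CCO")
        assert np.allclose(lt.gcn_forward(g, model)[0], lt.gcn_forward(g, back)[0])
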