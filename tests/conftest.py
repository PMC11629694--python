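import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lipidte as lt
from lipidte.gcn import GCNConfig, extract_embeddings, train_gcn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    """Default synthetic lipid library: 7 families x 20, planted activity."""
    return lt.generate_lipid_library()


@pytest.fixture(scope="session")
def cfp_embedding(library):
    return lt.embed_records(library, "cfp")


@pytest.fixture(scope="session")
def library_graphs(library):
    return [lt.build_mol_graph(r.smiles) for r in library]


@pytest.fixture(scope="session")
def gcn_embedding(library, library_graphs):
    """GCN trained on the synthetic library at reduced scale, then applied
    to every record."""
    labels = np.array([r.binary_label for r in library])
    tr, va, _ = lt.stratified_split(labels, seed=0)
    cfg = GCNConfig(hidden_dim=32, max_epochs=400, patience=100,
                    learning_rate=3e-3, seed=0, n_classes=2)
    model, _ = train_gcn(
        [library_graphs[i] for i in tr], labels[tr],
        [library_graphs[i] for i in va], labels[va], cfg,
    )
    return extract_embeddings(model, library_graphs, [r.id for r in library])


def random_molgraph(rng, n_max=8):
    """Random connected graph wrapped as a MolGraph with random features."""
    from lipidte.featurize import MolGraph, NODE_FEATURE_DIM

    n = int(rng.integers(1, n_max + 1))
    adj = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree keeps it connected
        j = order[int(rng.integers(0, i))]
        adj[order[i], j] = adj[j, order[i]] = 1
    for _ in range(int(rng.integers(0, n))):  # extra edges
        u, v = rng.integers(0, n, size=2)
        if u != v:
            adj[u, v] = adj[v, u] = 1
    return MolGraph(
        node_features=rng.normal(size=(n, NODE_FEATURE_DIM)),
        adjacency=adj,
        degrees=adj.sum(axis=1).astype(np.int64),
        atom_symbols=tuple("C" * n),
    )
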