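"""The three built-in molecular representations for one ionizable lipid.

A hydrogen-suppressed atom graph (75 features per heavy atom), a
count-based circular fingerprint (radius 2 folded into 2048 bins), and a
frozen registry of 200 physicochemical descriptors.
"""

import lipidte as lt

smiles = "CCCCCCCCCCCC(=O)OCCN(C)CCOC(=O)CCCCCCCCCCC"  # two-tailed amine lipid

graph = lt.build_mol_graph(smiles)
print(f"graph: {graph.n_nodes} heavy atoms, {graph.n_edges} bonds, "
      f"degree range {graph.degrees.min()}-{graph.degrees.max()}")
print(f"node features: {graph.node_features.shape} (one-hot blocks per atom)")

fp = lt.circular_fingerprint(smiles)
print(f"fingerprint: {fp.shape[0]} bins, {int(fp.sum())} environment counts, "
      f"{int((fp > 0).sum())} occupied bins, max count {int(fp.max())}")
# high max counts are the point: lipid tails repeat the same CH2 environment

registry = lt.load_descriptor_registry()
desc = lt.expert_descriptors(smiles)
print(f"descriptors: {desc.shape[0]} values, e.g. "
      f"MolWt={desc[registry.index('MolWt')]:.2f}, "
      f"MolLogP={desc[registry.index('MolLogP')]:.2f}")
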