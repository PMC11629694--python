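# Methods

## Problem and data model

The unit of analysis is one ionizable lipid, represented by its SMILES
string, with an optional raw activity value (RLU, relative light units — a
luciferase reporter proxy for transfection efficiency), optional derived
labels, and an optional lipid-family id. Labels derive from RLU through a
`LabelScheme`: binary satisfying at RLU ≥ 10 000, and four ordinal classes
from three strictly increasing cut points with half-open bins
[0,c₁), [c₁,c₂), [c₂,c₃), [c₃,∞). The "≥ cut ⇒ higher class" convention is
applied uniformly, so the binary label equals (multiclass class == 3)
whenever the binary cut is the top multiclass cut — which `derive_labels`
enforces when deriving both. The exact multiclass cut points are
dataset-dependent; the shipped defaults are RLU decades (10², 10³, 10⁴)
and are plain configuration, not constants.

SMILES are canonicalized at ingest. Duplicate canonical structures with
conflicting labels are reported and never merged — curated datasets
(structures re-drawn from figures) do contain such artifacts. A lenient
reader mode skips unparseable rows with a logged count; strict mode aborts
naming the row.

## Representations

**Atom graphs.** Hydrogen-suppressed: one node per heavy atom, one
undirected edge per covalent bond; multi-fragment inputs (salts) stay as
disconnected components unless restricted to the largest fragment. Each
node carries a 75-dim feature vector built from fixed one-hot blocks:
element over a 44-symbol vocabulary with a trailing "other" slot, degree
0–10 (clamped), implicit valence 0–6 (clamped), formal charge, radical
electron count, hybridization over {SP, SP2, SP3, SP3D, other},
aromaticity flag, and total hydrogen count 0–4 (clamped). Only the size
(75) and the ingredient categories (element, valence electrons,
hydrogenation, charge) are fixed by the modelling lineage; the exact
layout is pinned in `featurize.FEATURE_BLOCKS` and every one-hot block
sums to exactly one by construction.

**Count circular fingerprints.** Identifiers follow the iterative
Morgan/ECFP scheme: the radius-0 identifier hashes an atom's invariants
(atomic number, heavy degree, total H, formal charge, aromaticity, ring
membership); the radius-r identifier hashes the radius-(r−1) identifier
together with the sorted (bond order, neighbor identifier) pairs. Hashing
is a 64-bit BLAKE2b digest of the packed integer tuple, so fingerprints
are stable across runs and platforms. A radius is *realizable* for an atom
only while its neighborhood keeps growing (an isolated atom contributes
radius 0 only), and environments are deliberately **not** deduplicated:
each atom contributes one count per realizable radius, so the total count
equals Σ_atoms (#realizable radii) — an invariant the tests verify against
a brute-force BFS enumerator. This differs from fingerprint
implementations that collapse environments covering identical bond sets;
keeping every count is the intended semantics here because lipid tails
repeat the same environments many times and the repeat count is signal.
Folding is identifier mod bins (2048 default), collisions accepted.

**Expert descriptors.** A frozen, versioned registry of exactly 200 RDKit
descriptor names (`data/descriptor_registry_v1.txt`), shipped as an asset
because descriptor sets drift across backend releases; every name is
resolved at load time so a stale registry fails at startup, not per
molecule. The registry is the full RDKit 2024.09 descriptor list minus the
eight BCUT2D descriptors (NaN when partial-charge assignment fails), Ipc
(numerically overflows for large molecules), and qed (a composite
drug-likeness score, not a physicochemical property). Non-finite values
are zeroed with a logged warning. The molecule is recanonicalized before
computation: additive descriptors such as MolLogP otherwise differ in the
last floating-point ulp with atom input order, and the contract here is
bitwise determinism per canonical structure.

**External embeddings.** Matrices produced elsewhere (pretrained graph
transformers, SMILES language models) are imported from delimited files
with an id column; rows are joined to lipid tables by id, and duplicate
ids or non-finite values are errors. Dimension contracts (expert 200, cfp
2048, gcn 32) are enforced per method tag; external matrices may have any
width.

## The graph convolutional embedder

Propagation uses Â = A + I and D̃ = diag(rowsum Â), i.e. self-loops are
included in the degree matrix — the convention that guarantees positive
degrees and hence invertibility. Each convolution computes
ReLU([D̃^(−1/2) Â D̃^(−1/2) H W_bin(v)]_v) per node v, where
bin(v) = clamp(degree(v), 1, 5) selects one of five per-layer weight
matrices; one weight matrix per possible neighbor count is the only
reading of the degree-binned formulation consistent with its stated
purpose, and degrees above 5 (rare in hydrogen-suppressed organics) clamp
to the top bin. Dropout (default 0.3) applies to convolution outputs after
the ReLU, in training mode only. After the final convolution, node states
are sum-pooled — making the embedding invariant to node order — and a
dense layer maps the pooled vector to the 32-dim embedding; a single
linear-softmax head on the embedding provides the cross-entropy training
signal and is discarded after embedding extraction.

Unpublished details are configuration with documented defaults: hidden
width 64, optimizer full-batch Adam (β₁ 0.9, β₂ 0.999) at learning rate
1e-3, Glorot-uniform initialization. Training runs to 5000 epochs with
early stopping at patience 500 on validation loss by default; best-epoch
weights are restored and ties keep the earliest epoch. Everything is
seeded through one generator, so training is bitwise reproducible; the
hand-derived gradients are verified against finite differences in the
test suite, and the vectorized forward pass (all graphs packed into one
block-diagonal sparse propagation matrix) against a per-node loop oracle.

## Classification heads

LightGBM stands behind the `GBTConfig`/`ClassifierModel` surface (depth
maps to `max_depth` with `num_leaves = 2^depth`, deterministic
single-thread mode, `min_child_samples` 5 for small datasets). The frozen
multiclass configuration is depth 5, learning rate 0.005, 5000 iterations.
The binary task's grid (axes unpublished) defaults to
depth ∈ {4,5,6} × lr ∈ {0.005, 0.01, 0.05} × iterations ∈ {1000, 5000},
selected by validation AUC with ties broken toward fewer iterations, then
smaller depth, then smaller learning rate. No class reweighting: imbalance
is handled by the metric suite, not the loss. The classifier sees exactly
one embedding source per experiment — the ionizable lipid alone, never
formulation ratios or other components.

## Evaluation protocols

Per-fold metrics: AUC (binary, or one-vs-rest macro-averaged over classes
for which it is defined), balanced accuracy (mean per-class recall),
support-weighted F1, and the generalized multiclass MCC. AUC is reported
absent — not zero — when a fold's true labels contain fewer than two
distinct classes; aggregates average only defined values. The choice of
macro-averaging over *defined* one-vs-rest AUCs (rather than failing when
any class is missing) is what lets family holdout report partial results.

Protocols: (1) a stratified 80/10/10 train/val/test split at a fixed seed
when no external split file is supplied; (2) stratified k-fold CV
(default k = 5) with shuffled, seeded folds shared across every embedding
method, per-fold class counts within one of exact proportionality;
(3) leave-one-family-out holdout, one run per family, train and test
family sets disjoint by construction. Paired one-sided t-tests compare
two methods' fold metrics (alternative: mean difference > 0, k−1 degrees
of freedom); zero-variance positive differences report below the machine
floor, zero differences report p = 1. The test's null calibration
(≈5% rejections at α = 0.05 on equal-mean simulated fold metrics) is part
of the acceptance checks.

## Clustering

K-means (best of n_init = 10 seeded restarts by inertia) at k defaulting
to the number of families. NMI normalizes mutual information by the
arithmetic mean of the two partition entropies (geometric available); a
single-cluster partition has zero entropy and scores 0 by convention,
including when both partitions are constant. PCA (exact SVD) is the
built-in 2-D projector so the module is deterministic without optional
dependencies; any callable `(values, seed) → n×2` can be plugged in as an
external projector (e.g. UMAP).

## Synthetic library

The generator emulates the *structure* of a multi-tailed
ionizable-phospholipid library, not its chemistry: families are defined by
(tail count, zwitterion count) pairs — default seven families, (1,0) to
(4,1) — and each lipid is assembled as a valid SMILES from ester-linked
alkyl tails (lengths sampled per lipid from 6–16 carbons), optional
phosphocholine-like zwitterion fragments, and methyl padding distributed
over an amine backbone. Activity is planted as
log₁₀ RLU = 1.0 + 0.9·(tails) + 0.05·(mean tail carbons) − 0.5·(zwitterions)
plus Gaussian noise (SD 0.3 on the log scale), making RLU log-normal —
heavy-tailed like the real readout — and spanning roughly 10².5–10⁵ so
that the 10 000 binary cut separates high-tail-count families. The
coefficients were chosen once so that family 0 (single short tail) never
reaches satisfying activity, exercising the family-holdout rule that
single-class test families have no defined AUC.

What passing tests on this library do show: the representations carry the
tail-count signal, the pipeline recovers a planted monotone
structure–activity effect under cross-validation (AUC ≥ 0.95), collapses
to chance under label permutation, and the protocols behave exactly as
specified. What they do not show: performance on real lipid chemistry —
real libraries have correlated descriptors, activity cliffs,
assay-specific noise structure, and families whose differences are subtler
than tail count. Published benchmark numbers on the real 622-LNP dataset
additionally depend on external pretrained embedding models and are out of
scope here; external embedding files can be evaluated through the same
pipeline via `import_external_embeddings`.

## Problem sizes and numerical choices

Experiments on the synthetic library run at reduced scale as the package's
own choice for its test battery: GCN hidden width 32, max 400 epochs,
patience 100, learning rate 3e-3; boosted trees at 300 iterations
(learning rate 0.05) for signal recovery and 120 iterations for the
20-repeat permutation null. The reference-scale defaults (GCN 5000/500,
GBT 5000 at lr 0.005) remain the shipped configuration values. Recovery
AUC under these conditions is ≈0.95–0.99 depending on the noise draw.

Other numerical choices: cross-entropy clips probabilities to
[1e-12, 1] before the log and validates row normalization to 1e-6;
predicted probability rows are renormalized against backend round-off and
validated to 1e-9 in the metric suite; fingerprint hashing is 64-bit, so
folding collisions at 2048 bins are possible but rare and accepted;
K-means and PCA inherit scikit-learn's deterministic seeded behavior.

## Known limitations

* The GCN trains on one stratified split; when its embeddings are reused
  across CV folds, fold test lipids were visible (unlabeled, and labeled
  only if in the GCN's training split) during embedding training. This
  mirrors the upstream two-stage design; a fully nested variant would
  retrain the GCN inside every fold at ~5× cost.
* Sum pooling makes molecule embeddings grow with molecule size; functions
  of size that are not monotone (e.g. parity) are not representable, and
  very large lipids may dominate distance-based analyses.
* The fingerprint's no-deduplication semantics intentionally diverges from
  bit-vector ECFP conventions; comparisons against other software should
  use counts, not bits.
* Family assembly supports up to ~6 substituent slots; exotic architectures
  (branched backbones, cyclic cores) are out of the generator's scope.
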