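"""Molecular representations: atom graphs, count fingerprints, descriptors.

Three embedding routes are produced here, all keyed on the ionizable lipid's
SMILES alone:

* :func:`build_mol_graph` — the hydrogen-suppressed atom graph with a
  75-dimensional sparse feature vector per heavy atom, consumed by the graph
  convolutional embedder,
* :func:`circular_fingerprint` — count-based circular (Morgan) fingerprints,
  radius 2, folded into 2048 bins,
* :func:`expert_descriptors` — a pinned, ordered registry of 200 RDKit
  physicochemical/structural descriptors.

Externally precomputed embeddings (e.g. from pretrained graph transformers or
SMILES language models) are imported as delimited numeric files via
:func:`import_external_embeddings`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_io import LipidRecord, SmilesParseError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# atom features (75-dim, Duvenaud-lineage layout)
# ---------------------------------------------------------------------------

#: element one-hot vocabulary; the trailing "other" slot absorbs anything else
ATOM_SYMBOLS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "other",
)

_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    # 5th slot is a catch-all (SP3D2, S, unspecified, ...)
)

#: (name, length, is_onehot) blocks composing the 75-dim atom feature vector
FEATURE_BLOCKS: tuple[tuple[str, int, bool], ...] = (
    ("symbol", len(ATOM_SYMBOLS), True),   # 44
    ("degree", 11, True),                  # heavy-atom degree 0..10, clamped
    ("implicit_valence", 7, True),         # 0..6, clamped
    ("formal_charge", 1, False),
    ("radical_electrons", 1, False),
    ("hybridization", 5, True),            # SP, SP2, SP3, SP3D, other
    ("aromatic", 1, False),
    ("total_hydrogens", 5, True),          # 0..4, clamped
)

NODE_FEATURE_DIM = sum(n for _, n, _ in FEATURE_BLOCKS)
assert NODE_FEATURE_DIM == 75


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """75-dim feature vector for one heavy atom (element identity, valence
    electrons/hydrogenation, and charge state)."""
    v = np.zeros(NODE_FEATURE_DIM)
    off = 0

    sym = atom.GetSymbol()
    idx = ATOM_SYMBOLS.index(sym) if sym in ATOM_SYMBOLS else len(ATOM_SYMBOLS) - 1
    v[off + idx] = 1.0
    off += len(ATOM_SYMBOLS)

    v[off + min(atom.GetDegree(), 10)] = 1.0
    off += 11
    v[off + min(atom.GetImplicitValence(), 6)] = 1.0
    off += 7
    v[off] = float(atom.GetFormalCharge())
    off += 1
    v[off] = float(atom.GetNumRadicalElectrons())
    off += 1
    hyb = atom.GetHybridization()
    hyb_idx = _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 4
    v[off + hyb_idx] = 1.0
    off += 5
    v[off] = float(atom.GetIsAromatic())
    off += 1
    v[off + min(atom.GetTotalNumHs(), 4)] = 1.0
    return v


@dataclass
class MolGraph:
    """Hydrogen-suppressed molecular graph with per-node feature vectors."""

    node_features: np.ndarray  # (n, 75)
    adjacency: np.ndarray      # (n, n) binary, symmetric, zero diagonal
    degrees: np.ndarray        # (n,) row sums of adjacency
    atom_symbols: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def validate(self) -> None:
        n = self.n_nodes
        if n < 1:
            raise ValueError("graph must have at least one node")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.array_equal(self.degrees, self.adjacency.sum(axis=1)):
            raise ValueError("degrees must equal adjacency row sums")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(f"unparseable SMILES or no heavy atoms: {smiles!r}")
    return mol


def build_mol_graph(smiles: str, *, largest_fragment: bool = False) -> MolGraph:
    """Atom graph of a SMILES: nodes are heavy atoms, edges covalent bonds.

    Multi-fragment inputs (salts) are kept as separate components of one
    graph unless ``largest_fragment`` restricts to the biggest one.
    """
    mol = _mol_from_smiles(smiles)
    if largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    n = mol.GetNumAtoms()
    adj = np.zeros((n, n), dtype=np.int8)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    graph = MolGraph(
        node_features=feats,
        adjacency=adj,
        degrees=adj.sum(axis=1).astype(np.int64),
        atom_symbols=tuple(a.GetSymbol() for a in mol.GetAtoms()),
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# count-based circular fingerprints
# ---------------------------------------------------------------------------

def _stable_hash(payload: tuple) -> int:
    """Deterministic 64-bit hash of a tuple of nonnegative ints (run-independent)."""
    data = np.array([x & 0xFFFFFFFFFFFFFFFF for x in payload], dtype=np.uint64).tobytes()
    return int.from_bytes(hashlib.blake2b(data, digest_size=8).digest(), "big")


def _initial_invariants(mol: Chem.Mol) -> list[int]:
    inv = []
    for atom in mol.GetAtoms():
        inv.append(
            _stable_hash(
                (
                    atom.GetAtomicNum(),
                    atom.GetDegree(),
                    atom.GetTotalNumHs(),
                    atom.GetFormalCharge(),
                    int(atom.GetIsAromatic()),
                    int(atom.IsInRing()),
                )
            )
        )
    return inv


def morgan_environments(smiles: str, radius: int = 2) -> list[tuple[int, int, int]]:
    """Enumerate ``(atom_index, radius, identifier)`` circular environments.

    Identifiers follow the iterative Morgan/ECFP scheme: the radius-r
    identifier of an atom hashes its radius-(r-1) identifier together with the
    sorted (bond-order, neighbor identifier) pairs.  A radius is *realizable*
    for an atom only while its neighborhood keeps growing (an isolated atom
    contributes the radius-0 environment only).  Environments are not
    deduplicated: each atom contributes one count per realizable radius, so
    repeating substructures — ubiquitous in lipid tails — accumulate counts.
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = int(bond.GetBondType())
        neighbors[i].append((order, j))
        neighbors[j].append((order, i))

    dist = Chem.GetDistanceMatrix(mol)
    ids = _initial_invariants(mol)
    out: list[tuple[int, int, int]] = [(a, 0, ids[a]) for a in range(n)]
    for r in range(1, radius + 1):
        nxt = [
            _stable_hash(
                (r, ids[a]) + tuple(x for o, j in sorted(
                    ((o, ids[j]) for o, j in neighbors[a])) for x in (o, j))
            )
            for a in range(n)
        ]
        for a in range(n):
            # realizable iff some atom sits at exactly distance r from a
            if np.any(dist[a] == r):
                out.append((a, r, nxt[a]))
        ids = nxt
    return out


def circular_fingerprint(smiles: str, radius: int = 2, bins: int = 2048) -> np.ndarray:
    """Count-based circular fingerprint folded into ``bins`` (default 2048).

    Bin b accumulates the occurrence counts of every circular substructure
    (radii 0..``radius`` around each atom) whose identifier folds to b;
    folding collisions are accepted, standard semantics.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    fp = np.zeros(bins, dtype=np.int64)
    for _, _, ident in morgan_environments(smiles, radius):
        fp[ident % bins] += 1
    return fp


# ---------------------------------------------------------------------------
# expert descriptors
# ---------------------------------------------------------------------------

EXPERT_DIM = 200
_REGISTRY_ASSET = "descriptor_registry_v1.txt"


def load_descriptor_registry(path: str | Path | None = None) -> tuple[str, ...]:
    """Load the frozen, ordered 200-descriptor registry.

    The registry is shipped as a versioned asset because descriptor sets
    drift across cheminformatics-backend releases; every name is resolved
    against the backend at load time, so a stale registry fails at startup
    rather than per molecule.
    """
    if path is None:
        text = resources.files("lipidte.data").joinpath(_REGISTRY_ASSET).read_text()
    else:
        text = Path(path).read_text()
    names = tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    available = dict(Descriptors._descList)
    missing = [n for n in names if n not in available]
    if missing:
        raise ValueError(f"descriptor registry names not resolvable by backend: {missing}")
    return names


_DESC_FUNCS: dict[str, Callable] = dict(Descriptors._descList)


def expert_descriptors(
    smiles: str, registry: Sequence[str] | None = None
) -> np.ndarray:
    """Vector of 200 physicochemical descriptors in registry order.

    Non-finite descriptor values are replaced by 0 with a logged warning.
    """
    names = tuple(registry) if registry is not None else load_descriptor_registry()
    if len(names) != EXPERT_DIM:
        raise ValueError(f"registry must contain exactly {EXPERT_DIM} names, got {len(names)}")
    # recanonicalize so additive descriptors are bitwise atom-order invariant
    mol = _mol_from_smiles(Chem.MolToSmiles(_mol_from_smiles(smiles)))
    vals = np.empty(len(names))
    for i, name in enumerate(names):
        try:
            vals[i] = float(_DESC_FUNCS[name](mol))
        except KeyError:
            raise ValueError(f"descriptor {name!r} not resolvable by backend") from None
    bad = ~np.isfinite(vals)
    if bad.any():
        logger.warning(
            "non-finite descriptors set to 0 for %s: %s",
            smiles, [names[i] for i in np.flatnonzero(bad)],
        )
        vals[bad] = 0.0
    return vals


# ---------------------------------------------------------------------------
# embedding matrices
# ---------------------------------------------------------------------------

_METHOD_DIMS = {"expert": EXPERT_DIM, "cfp": 2048, "gcn": 32}


@dataclass
class EmbeddingMatrix:
    """An n x d numeric embedding with per-row record ids and a method tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    method: str = field(default="external:unknown")

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids vs {self.values.shape[0]} embedding rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids in embedding matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite entries")
        expect = _METHOD_DIMS.get(self.method)
        if expect is not None and self.dim != expect:
            raise ValueError(
                f"method {self.method!r} requires dim {expect}, got {self.dim}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        """Rows reordered/selected by id (keyed join)."""
        index = {rid: i for i, rid in enumerate(self.ids)}
        missing = [r for r in ids if str(r) not in index]
        if missing:
            raise KeyError(f"ids missing from embedding matrix: {missing[:5]}")
        rows = [index[str(r)] for r in ids]
        return EmbeddingMatrix(
            ids=tuple(str(r) for r in ids), values=self.values[rows], method=self.method
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=[f"e{j+1}" for j in range(self.dim)])
        df.insert(0, "id", list(self.ids))
        df.to_csv(path, index=False)


def embed_records(
    records: Iterable[LipidRecord], method: str, registry: Sequence[str] | None = None
) -> EmbeddingMatrix:
    """Compute an expert-descriptor or fingerprint embedding for records."""
    records = list(records)
    ids = tuple(r.id for r in records)
    if method == "expert":
        names = tuple(registry) if registry is not None else load_descriptor_registry()
        values = np.stack([expert_descriptors(r.smiles, names) for r in records])
    elif method == "cfp":
        values = np.stack([circular_fingerprint(r.smiles) for r in records]).astype(float)
    else:
        raise ValueError(f"unknown embedding method {method!r}; use 'expert' or 'cfp'")
    return EmbeddingMatrix(ids=ids, values=values, method=method)


def import_external_embeddings(path: str | Path, *, id_column: str = "id") -> EmbeddingMatrix:
    """Load an externally precomputed embedding (e.g. graph-transformer or
    SMILES-language-model output) from a delimited numeric file.

    The file must have an id column and constant row width; the method tag is
    ``external:<basename>``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        if df.columns[0].lower() in ("id", "record_id"):
            id_column = df.columns[0]
        else:
            raise ValueError(f"{path}: no {id_column!r} column")
    ids = tuple(str(x) for x in df[id_column])
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate ids")
    values = df.drop(columns=[id_column]).to_numpy(dtype=float)
    if values.shape[1] < 1 or not np.isfinite(values).all():
        raise ValueError(f"{path}: ragged or non-numeric embedding rows")
    return EmbeddingMatrix(ids=ids, values=values, method=f"external:{path.stem}")
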