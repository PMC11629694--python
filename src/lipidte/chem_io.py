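"""Lipid table I/O, SMILES canonicalization, and transfection-efficiency labels.

The experimental readout behind every label is RLU activity (relative light
units, a luciferase reporter proxy for transfection efficiency).  Two label
schemes are supported:

* binary — satisfying (1) iff RLU >= ``binary_cut`` (default 10 000),
* multiclass — four ordinal activity classes defined by three ordered RLU
  cut points; a value equal to a cut belongs to the higher class, mirroring
  the inclusive ">=" convention of the binary rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit logs every parse failure to stderr; we report them ourselves.
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecule with >=1 heavy atom."""


class SchemaError(ValueError):
    """A required column is missing from a lipid table."""


class EmptyTableError(ValueError):
    """A lipid table contains no data rows."""


class ConfigurationError(ValueError):
    """A label scheme or pipeline configuration is internally inconsistent."""


@dataclass(frozen=True)
class LabelScheme:
    """RLU thresholds mapping raw activity to TE classes.

    ``multiclass_cuts`` must be strictly increasing; the exact multiclass cut
    points are dataset-dependent configuration (defaults are RLU decades with
    the top cut equal to the binary cut).
    """

    binary_cut: float = 10_000.0
    multiclass_cuts: tuple[float, ...] = (100.0, 1_000.0, 10_000.0)

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.multiclass_cuts)
        if len(cuts) != 3:
            raise ConfigurationError(
                f"multiclass_cuts must contain exactly 3 thresholds, got {len(cuts)}"
            )
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ConfigurationError(f"multiclass_cuts must be strictly increasing: {cuts}")
        object.__setattr__(self, "multiclass_cuts", cuts)
        object.__setattr__(self, "binary_cut", float(self.binary_cut))

    @property
    def binary_cut_is_multiclass_cut(self) -> bool:
        return any(np.isclose(self.binary_cut, c) for c in self.multiclass_cuts)


@dataclass
class LipidRecord:
    """One ionizable lipid: identifier, structure, activity, and labels."""

    id: str
    smiles: str
    rlu: float | None = None
    binary_label: int | None = None
    multiclass_label: int | None = None
    family: int | None = None

    def __post_init__(self) -> None:
        if self.rlu is not None:
            self.rlu = float(self.rlu)
            if self.rlu < 0:
                raise ValueError(f"record {self.id!r}: RLU must be nonnegative, got {self.rlu}")
        if self.multiclass_label is not None and self.multiclass_label not in (0, 1, 2, 3):
            raise ValueError(
                f"record {self.id!r}: multiclass_label must be in {{0,1,2,3}}, "
                f"got {self.multiclass_label}"
            )
        if self.binary_label is not None and self.binary_label not in (0, 1):
            raise ValueError(
                f"record {self.id!r}: binary_label must be in {{0,1}}, got {self.binary_label}"
            )


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit's canonical SMILES; idempotent, invariant to atom order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(f"unparseable SMILES or no heavy atoms: {smiles!r}")
    return Chem.MolToSmiles(mol)


def assign_binary_label(rlu: float, scheme: LabelScheme = LabelScheme()) -> int:
    """1 (satisfying TE) iff ``rlu >= scheme.binary_cut``, else 0."""
    if rlu < 0:
        raise ValueError(f"RLU must be nonnegative, got {rlu}")
    return int(rlu >= scheme.binary_cut)


def assign_multiclass_label(rlu: float, scheme: LabelScheme = LabelScheme()) -> int:
    """Ordinal class 0..3 of the half-open RLU bin containing ``rlu``.

    Bins are ``[0,c1) [c1,c2) [c2,c3) [c3,inf)`` so a value on a cut falls in
    the higher class, consistent with the binary ">= cut" convention.
    """
    if rlu < 0:
        raise ValueError(f"RLU must be nonnegative, got {rlu}")
    return int(np.searchsorted(scheme.multiclass_cuts, rlu, side="right"))


def derive_labels(
    records: Iterable[LipidRecord],
    scheme: LabelScheme = LabelScheme(),
    *,
    binary: bool = True,
    multiclass: bool = True,
) -> list[LipidRecord]:
    """Return copies of ``records`` with labels (re)derived from RLU.

    Records without an RLU value are passed through unchanged.  When both
    schemes are derived together the binary cut must coincide with one
    multiclass cut, so that binary_label == (multiclass_label == 3) holds
    whenever the shared cut is the top one.
    """
    if binary and multiclass and not scheme.binary_cut_is_multiclass_cut:
        raise ConfigurationError(
            f"binary cut {scheme.binary_cut} must coincide with one multiclass cut "
            f"{scheme.multiclass_cuts} when both label schemes are derived"
        )
    out = []
    for rec in records:
        if rec.rlu is None:
            out.append(replace(rec))
            continue
        rec = replace(rec)
        if binary:
            rec.binary_label = assign_binary_label(rec.rlu, scheme)
        if multiclass:
            rec.multiclass_label = assign_multiclass_label(rec.rlu, scheme)
        out.append(rec)
    return out


#: default column-name mapping for lipid tables
DEFAULT_SCHEMA: Mapping[str, str] = {
    "id": "id",
    "smiles": "smiles",
    "rlu": "rlu",
    "binary_label": "binary_label",
    "multiclass_label": "multiclass_label",
    "family": "family",
}


def read_lnp_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
    sep: str | None = None,
) -> list[LipidRecord]:
    """Read a delimited lipid table into validated records.

    Only the ``smiles`` column is mandatory; ``id`` defaults to the row
    number.  SMILES are canonicalized at ingest.  In strict mode an
    unparseable SMILES aborts with an error naming the row; in lenient mode
    the row is skipped and the skip count logged.  Duplicate canonical SMILES
    carrying conflicting labels are reported via warning, never merged.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise EmptyTableError(f"{path}: no data rows")
    if schema["smiles"] not in df.columns:
        raise SchemaError(f"{path}: missing required column {schema['smiles']!r}")

    def _get(row, key, cast):
        col = schema[key]
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    records: list[LipidRecord] = []
    n_skipped = 0
    for i, row in df.iterrows():
        raw_smiles = row[schema["smiles"]]
        rec_id = _get(row, "id", str) or str(i)
        try:
            smiles = canonicalize_smiles(str(raw_smiles))
        except SmilesParseError as exc:
            if strict:
                raise SmilesParseError(f"{path} row {i} (id {rec_id!r}): {exc}") from exc
            n_skipped += 1
            continue
        records.append(
            LipidRecord(
                id=rec_id,
                smiles=smiles,
                rlu=_get(row, "rlu", float),
                binary_label=_get(row, "binary_label", int),
                multiclass_label=_get(row, "multiclass_label", int),
                family=_get(row, "family", int),
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d rows with unparseable SMILES", path, n_skipped)
    if not records:
        raise EmptyTableError(f"{path}: no rows with valid SMILES")
    _warn_conflicting_duplicates(records)
    return records


def _warn_conflicting_duplicates(records: Sequence[LipidRecord]) -> None:
    by_smiles: dict[str, LipidRecord] = {}
    for rec in records:
        prev = by_smiles.setdefault(rec.smiles, rec)
        if prev is not rec:
            for field in ("binary_label", "multiclass_label"):
                a, b = getattr(prev, field), getattr(rec, field)
                if a is not None and b is not None and a != b:
                    logger.warning(
                        "duplicate canonical SMILES %s with conflicting %s: "
                        "records %r (%s) vs %r (%s)",
                        rec.smiles, field, prev.id, a, rec.id, b,
                    )


def write_lnp_table(
    records: Sequence[LipidRecord], path: str | Path, *, sep: str | None = None
) -> None:
    """Write records as a delimited table (columns per :data:`DEFAULT_SCHEMA`)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "rlu": [r.rlu for r in records],
            "binary_label": [r.binary_label for r in records],
            "multiclass_label": [r.multiclass_label for r in records],
            "family": [r.family for r in records],
        }
    )
    # keep integer columns integral in the round trip
    for col in ("binary_label", "multiclass_label", "family"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, sep=sep, index=False)
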