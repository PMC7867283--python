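"""Compound library ingestion and activity labelling.

Compound activity is expressed on the pLC50 scale (-log10 of the lethal
concentration 50); a compound is called *active* when its pLC50 is at or
above a potency threshold (default 4.5). Libraries arrive either as CSV
(``compound_id``, optional ``smiles``, ``plc50``, ``species_tag``) or as an
SDF with the activity in a named data field. Structure handling is purely
syntactic: SMILES/SDF blocks are validated with RDKit but never normalized
(no salt stripping, no tautomer canonicalization).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

DEFAULT_PLC50_THRESHOLD = 4.5

_CSV_COLUMNS = ("compound_id", "smiles", "plc50", "species_tag")

RDLogger.DisableLog("rdApp.*")


class Species(str, Enum):
    """Target species tag for an activity record."""

    APHIS = "aphis"
    DROSOPHILA = "drosophila"


class Label(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class LibraryError(ValueError):
    """Malformed or inconsistent compound library input."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifier, optional structure, optional potency."""

    compound_id: str
    smiles: str | None = None
    plc50: float | None = None
    species_tag: Species | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise LibraryError("compound_id must be a non-empty string")
        if self.plc50 is not None and not math.isfinite(self.plc50):
            raise LibraryError(
                f"compound {self.compound_id!r}: pLC50 must be finite, got {self.plc50!r}"
            )


@dataclass(frozen=True)
class LabeledCompound:
    """A compound with its active/inactive class assignment."""

    record: CompoundRecord
    label: Label

    @property
    def is_active(self) -> bool:
        return self.label is Label.ACTIVE


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for cid in ids:
        if cid in seen:
            raise LibraryError(f"duplicate compound_id {cid!r}")
        seen.add(cid)


def read_library_csv(stream: str | io.TextIOBase) -> list[CompoundRecord]:
    """Read a compound library from CSV content.

    Expects a header row with at least ``compound_id``; ``smiles``,
    ``plc50`` and ``species_tag`` are optional columns. Order is preserved
    and duplicate identifiers are rejected.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        df = pd.read_csv(stream, dtype={"compound_id": str})
    except pd.errors.EmptyDataError:
        return []
    if "compound_id" not in df.columns:
        raise LibraryError("CSV is missing the mandatory 'compound_id' column")
    records: list[CompoundRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        plc50 = row.get("plc50")
        if plc50 is not None and pd.isna(plc50):
            plc50 = None
        if plc50 is not None:
            try:
                plc50 = float(plc50)
            except (TypeError, ValueError) as exc:
                raise LibraryError(f"row {idx}: non-numeric pLC50 {plc50!r}") from exc
        smiles = row.get("smiles")
        if smiles is not None and (pd.isna(smiles) or smiles == ""):
            smiles = None
        if smiles is not None and Chem.MolFromSmiles(str(smiles)) is None:
            raise LibraryError(f"row {idx}: unparsable SMILES {smiles!r}")
        tag = row.get("species_tag")
        if tag is not None and pd.isna(tag):
            tag = None
        species = Species(str(tag)) if tag is not None else None
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                smiles=None if smiles is None else str(smiles),
                plc50=plc50,
                species_tag=species,
            )
        )
    _check_unique_ids([r.compound_id for r in records])
    return records


def read_library_sdf(
    stream: str | io.TextIOBase,
    *,
    id_field: str | None = None,
    plc50_field: str = "pLC50",
) -> list[CompoundRecord]:
    """Read a compound library from SDF (V2000) content.

    The identifier is taken from ``id_field`` when given, otherwise from the
    molecule title line; the activity from the ``plc50_field`` data field
    when present.
    """
    if not isinstance(stream, str):
        stream = stream.read()
    if not stream.strip():
        return []
    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier()
    supplier.SetData(stream, sanitize=True, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise LibraryError(f"molecule {idx}: unparsable SDF record")
        if id_field is not None:
            if not mol.HasProp(id_field):
                raise LibraryError(f"molecule {idx}: missing id field {id_field!r}")
            cid = mol.GetProp(id_field)
        else:
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not cid:
            raise LibraryError(f"molecule {idx}: empty identifier")
        plc50 = None
        if mol.HasProp(plc50_field):
            try:
                plc50 = float(mol.GetProp(plc50_field))
            except ValueError as exc:
                raise LibraryError(
                    f"molecule {idx}: non-numeric {plc50_field} "
                    f"{mol.GetProp(plc50_field)!r}"
                ) from exc
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=Chem.MolToSmiles(mol),
                plc50=plc50,
            )
        )
    _check_unique_ids([r.compound_id for r in records])
    return records


def read_library(stream: str | io.TextIOBase, fmt: str = "csv", **kwargs) -> list[CompoundRecord]:
    """Read a compound library in the declared format (``csv`` or ``sdf``)."""
    if fmt == "csv":
        return read_library_csv(stream, **kwargs)
    if fmt == "sdf":
        return read_library_sdf(stream, **kwargs)
    raise LibraryError(f"unknown library format {fmt!r}")


def write_library_csv(records: Iterable[CompoundRecord]) -> str:
    """Serialize records back to the CSV dialect read_library_csv accepts."""
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "plc50": r.plc50,
            "species_tag": r.species_tag.value if r.species_tag else None,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(_CSV_COLUMNS))
    return df.to_csv(index=False, float_format="%.6f")


def label_activity(
    records: Sequence[CompoundRecord],
    threshold: float = DEFAULT_PLC50_THRESHOLD,
) -> list[LabeledCompound]:
    """Assign active/inactive classes by the pLC50 threshold.

    A compound is active iff ``plc50 >= threshold`` (the boundary value is
    active). Records without a pLC50 cannot be labelled and raise an error
    naming every offending identifier.
    """
    missing = [r.compound_id for r in records if r.plc50 is None]
    if missing:
        raise LibraryError(f"records without pLC50 cannot be labelled: {missing}")
    return [
        LabeledCompound(
            record=r,
            label=Label.ACTIVE if r.plc50 >= threshold else Label.INACTIVE,
        )
        for r in records
    ]


__all__ = [
    "DEFAULT_PLC50_THRESHOLD",
    "CompoundRecord",
    "LabeledCompound",
    "Label",
    "LibraryError",
    "Species",
    "label_activity",
    "read_library",
    "read_library_csv",
    "read_library_sdf",
    "write_library_csv",
]
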