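"""Docking score tables and their normalization into activity probabilities.

Docking output is consumed, never computed: each table carries per-ligand
binding energies for one enzyme (MolDock-style scores, kcal/mol scale, more
negative = stronger binding) together with the energy of a reference
inhibitor (a commercial insecticide co-crystallized or re-docked into the
same site). A ligand is *potentially active* only when its energy is
strictly below the reference inhibitor's, and its docking probability is
the energy ratio

    Prob_Dc = E_lig / E_mlig      (only when E_lig < E_inib)

where E_mlig is the lowest (best) energy over the screened set, so
Prob_Dc lies in (0, 1] and equals 1 exactly for the best-ranked ligand.
Secondary (GoldScore-style, higher = stronger) scores are carried through
for reporting but never enter the probability.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

NOT_ACTIVE = None  # marker returned when E_lig does not beat the reference


class DockingTableError(ValueError):
    """Malformed or inconsistent docking score table."""


@dataclass(frozen=True)
class DockingScoreTable:
    """Per-enzyme ligand energies plus one reference inhibitor energy."""

    enzyme_id: str
    ligand_scores: Mapping[str, float]
    reference_inhibitor_score: float
    reference_id: str | None = None
    heavy_atoms: Mapping[str, int] | None = None
    secondary_scores: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.reference_inhibitor_score):
            raise DockingTableError(
                f"{self.enzyme_id}: reference inhibitor score must be finite"
            )
        for cid, score in self.ligand_scores.items():
            if not math.isfinite(score):
                raise DockingTableError(f"{self.enzyme_id}: non-finite score for {cid!r}")

    @property
    def e_mlig(self) -> float:
        """Lowest (best) ligand energy over the screened set."""
        if not self.ligand_scores:
            raise DockingTableError(f"{self.enzyme_id}: empty table has no minimum energy")
        return min(self.ligand_scores.values())


@dataclass(frozen=True)
class DockingCall:
    """Activity call for one ligand at one enzyme."""

    compound_id: str
    enzyme_id: str
    score: float
    is_potentially_active: bool
    prob_dc: float | None
    ligand_efficiency: float | None = None

    def __post_init__(self) -> None:
        if self.is_potentially_active != (self.prob_dc is not None):
            raise DockingTableError(
                f"{self.compound_id}: prob_dc must be present iff the call is active"
            )
        if self.prob_dc is not None and not 0.0 < self.prob_dc <= 1.0:
            raise DockingTableError(
                f"{self.compound_id}: prob_dc {self.prob_dc} outside (0, 1]"
            )


def read_docking_tables(stream: str | io.TextIOBase) -> dict[str, DockingScoreTable]:
    """Read one or more per-enzyme docking tables from long-format CSV.

    Columns: ``compound_id``, ``enzyme_id``, ``score``, optional
    ``heavy_atoms``, optional ``secondary_score``, and ``is_reference``
    (0/1). Each enzyme must carry exactly one reference row (the
    insecticide); the reference is excluded from the ligand scores.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, dtype={"compound_id": str, "enzyme_id": str})
    required = {"compound_id", "enzyme_id", "score", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise DockingTableError(f"docking CSV is missing columns: {sorted(missing)}")
    tables: dict[str, DockingScoreTable] = {}
    for enzyme_id, group in df.groupby("enzyme_id", sort=False):
        scores: dict[str, float] = {}
        heavy: dict[str, int] = {}
        secondary: dict[str, float] = {}
        ref_score: float | None = None
        ref_id: str | None = None
        for idx, row in group.iterrows():
            try:
                score = float(row["score"])
            except (TypeError, ValueError) as exc:
                raise DockingTableError(
                    f"row {idx} ({row['compound_id']}/{enzyme_id}): "
                    f"non-numeric score {row['score']!r}"
                ) from exc
            if math.isnan(score):
                raise DockingTableError(
                    f"row {idx} ({row['compound_id']}/{enzyme_id}): missing score"
                )
            if int(row["is_reference"]):
                if ref_score is not None:
                    raise DockingTableError(
                        f"{enzyme_id}: more than one reference row flagged"
                    )
                ref_score, ref_id = score, str(row["compound_id"])
                continue
            cid = str(row["compound_id"])
            if cid in scores:
                raise DockingTableError(f"{enzyme_id}: duplicate ligand {cid!r}")
            scores[cid] = score
            if "heavy_atoms" in group.columns and not pd.isna(row["heavy_atoms"]):
                heavy[cid] = int(row["heavy_atoms"])
            if "secondary_score" in group.columns and not pd.isna(row["secondary_score"]):
                secondary[cid] = float(row["secondary_score"])
        if ref_score is None:
            raise DockingTableError(f"{enzyme_id}: no reference inhibitor row flagged")
        tables[str(enzyme_id)] = DockingScoreTable(
            enzyme_id=str(enzyme_id),
            ligand_scores=scores,
            reference_inhibitor_score=ref_score,
            reference_id=ref_id,
            heavy_atoms=heavy or None,
            secondary_scores=secondary or None,
        )
    return tables


def read_docking_table(
    stream: str | io.TextIOBase, enzyme_id: str | None = None
) -> DockingScoreTable:
    """Read a single-enzyme docking table (see :func:`read_docking_tables`)."""
    tables = read_docking_tables(stream)
    if enzyme_id is not None:
        if enzyme_id not in tables:
            raise DockingTableError(f"enzyme {enzyme_id!r} not present in table")
        return tables[enzyme_id]
    if len(tables) != 1:
        raise DockingTableError(
            f"expected a single enzyme, found {sorted(tables)}; pass enzyme_id"
        )
    return next(iter(tables.values()))


def docking_probability(e_lig: float, e_mlig: float, e_inib: float) -> float | None:
    """Normalize a docking energy into an activity probability.

    Returns ``e_lig / e_mlig`` in (0, 1] when ``e_lig < e_inib`` (strictly
    better binding than the reference inhibitor), otherwise the not-active
    marker ``None``. Energies must be negative (attractive binding): a
    positive or zero score would push the ratio outside (0, 1] and is
    rejected.
    """
    if e_mlig == 0:
        raise DockingTableError("E_mlig must be non-zero")
    if e_lig >= 0 or e_mlig >= 0:
        raise DockingTableError(
            f"docking energies must be negative, got E_lig={e_lig}, E_mlig={e_mlig}"
        )
    if e_lig < e_mlig:
        raise DockingTableError(
            f"E_lig={e_lig} below the set minimum E_mlig={e_mlig}; "
            "E_mlig must be the minimum over the screened set"
        )
    if not e_lig < e_inib:
        return NOT_ACTIVE
    return e_lig / e_mlig


def ligand_efficiency(score: float, heavy_atoms: int) -> float:
    """Docking score per heavy (non-hydrogen) atom, same sign as the score."""
    if heavy_atoms < 1:
        raise DockingTableError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return score / heavy_atoms


def call_actives(table: DockingScoreTable) -> list[DockingCall]:
    """Per-ligand activity calls for one enzyme.

    The minimum energy E_mlig is taken over this table's ligands, so the
    screened set supplied here defines the normalization scope. One call
    per ligand, in table order; active calls carry Prob_Dc.
    """
    if not table.ligand_scores:
        raise DockingTableError(f"{table.enzyme_id}: cannot call actives on an empty table")
    e_mlig = table.e_mlig
    calls: list[DockingCall] = []
    for cid, score in table.ligand_scores.items():
        prob = docking_probability(score, e_mlig, table.reference_inhibitor_score)
        le = None
        if table.heavy_atoms and cid in table.heavy_atoms:
            le = ligand_efficiency(score, table.heavy_atoms[cid])
        calls.append(
            DockingCall(
                compound_id=cid,
                enzyme_id=table.enzyme_id,
                score=score,
                is_potentially_active=prob is not None,
                prob_dc=prob,
                ligand_efficiency=le,
            )
        )
    return calls


def write_docking_tables_csv(tables: Mapping[str, DockingScoreTable]) -> str:
    """Serialize tables to the long-format CSV read_docking_tables accepts."""
    rows = []
    for table in tables.values():
        for cid, score in table.ligand_scores.items():
            rows.append(
                {
                    "compound_id": cid,
                    "enzyme_id": table.enzyme_id,
                    "score": score,
                    "heavy_atoms": (table.heavy_atoms or {}).get(cid),
                    "secondary_score": (table.secondary_scores or {}).get(cid),
                    "is_reference": 0,
                }
            )
        rows.append(
            {
                "compound_id": table.reference_id or "reference",
                "enzyme_id": table.enzyme_id,
                "score": table.reference_inhibitor_score,
                "heavy_atoms": None,
                "secondary_score": None,
                "is_reference": 1,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "enzyme_id",
            "score",
            "heavy_atoms",
            "secondary_score",
            "is_reference",
        ],
    )
    return df.to_csv(index=False)


__all__ = [
    "NOT_ACTIVE",
    "DockingCall",
    "DockingScoreTable",
    "DockingTableError",
    "call_actives",
    "docking_probability",
    "ligand_efficiency",
    "read_docking_table",
    "read_docking_tables",
    "write_docking_tables_csv",
]
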