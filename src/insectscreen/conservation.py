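"""Alignment-derived conservation statistics.

Given a pre-computed multiple protein alignment (aligned FASTA), two
statistics are reported: pairwise percent identity, and the fraction of a
template's active-site residues conserved in a query sequence. Alignment
construction itself is out of scope — any aligner's gapped FASTA output is
accepted.

Identity convention: identical columns divided by columns where at least
one of the pair carries a residue (gap-gap columns excluded). An optional
flag additionally trims columns covered by either sequence's terminal gap
runs, mirroring the common practice of excluding unshared end regions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

from Bio import AlignIO

GAP = "-"
_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO")


class AlignmentError(ValueError):
    """Invalid alignment or site specification."""


@dataclass(frozen=True)
class AlignedSequences:
    """Equal-length gapped amino-acid sequences keyed by identifier."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - _AA - {GAP}
            if bad:
                raise AlignmentError(f"sequence {sid!r}: invalid characters {sorted(bad)}")

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)].upper()
        except ValueError as exc:
            raise AlignmentError(f"unknown sequence id {seq_id!r}") from exc

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_alignment(stream: str | io.TextIOBase) -> AlignedSequences:
    """Read an aligned FASTA into an AlignedSequences container."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    aln = AlignIO.read(stream, "fasta")
    return AlignedSequences(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq) for rec in aln),
    )


@dataclass(frozen=True)
class SitePositions:
    """Active-site residues in a template's ungapped 1-based coordinates."""

    template_id: str
    positions: tuple[int, ...]
    expected_residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.expected_residues):
            raise AlignmentError("positions and expected residues differ in length")
        if any(p < 1 for p in self.positions):
            raise AlignmentError("site positions are 1-based and must be >= 1")
        if len(set(self.positions)) != len(self.positions):
            raise AlignmentError("duplicate site positions")


def _terminal_gap_mask(row: str) -> list[bool]:
    """True for columns inside the leading/trailing gap runs of a row."""
    n = len(row)
    mask = [False] * n
    i = 0
    while i < n and row[i] == GAP:
        mask[i] = True
        i += 1
    j = n - 1
    while j >= 0 and row[j] == GAP:
        mask[j] = True
        j -= 1
    return mask


def percent_identity(
    alignment: AlignedSequences,
    id_a: str,
    id_b: str,
    *,
    trim_terminal_gaps: bool = False,
) -> float:
    """Pairwise percent identity between two aligned sequences.

    100 x (identical residue columns) / (columns where at least one of the
    pair has a residue). With ``trim_terminal_gaps`` the columns spanned by
    either sequence's terminal gap runs are excluded first.
    """
    a = alignment.row(id_a)
    b = alignment.row(id_b)
    excluded = [False] * len(a)
    if trim_terminal_gaps:
        mask_a = _terminal_gap_mask(a)
        mask_b = _terminal_gap_mask(b)
        excluded = [ma or mb for ma, mb in zip(mask_a, mask_b)]
    identical = 0
    comparable = 0
    for ca, cb, skip in zip(a, b, excluded):
        if skip or (ca == GAP and cb == GAP):
            continue
        comparable += 1
        if ca == cb and ca != GAP:
            identical += 1
    if comparable == 0:
        raise AlignmentError(f"no comparable columns between {id_a!r} and {id_b!r}")
    return 100.0 * identical / comparable


def ungapped_to_column(row: str, position: int) -> int:
    """Map a 1-based ungapped position to its 0-based alignment column."""
    count = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            count += 1
            if count == position:
                return col
    raise AlignmentError(
        f"position {position} beyond ungapped length {count}"
    )


def site_conservation(
    alignment: AlignedSequences, sites: SitePositions, query_id: str
) -> float:
    """Percent of template active-site residues conserved in the query.

    Each template site position is mapped to its alignment column; a site
    counts as conserved when the query carries the same residue there. A
    gap in the query at a site column counts as not conserved. Expected
    residues, when given, are checked against the template sequence.
    """
    template = alignment.row(sites.template_id)
    query = alignment.row(query_id)
    if not sites.positions:
        raise AlignmentError("empty site list")
    conserved = 0
    for pos, expected in zip(sites.positions, sites.expected_residues):
        col = ungapped_to_column(template, pos)
        t_res = template[col]
        if expected and t_res != expected.upper():
            raise AlignmentError(
                f"template {sites.template_id!r} position {pos}: expected "
                f"{expected!r}, found {t_res!r}"
            )
        if query[col] == t_res:
            conserved += 1
    return 100.0 * conserved / len(sites.positions)


def read_sites_csv(
    stream: str | io.TextIOBase, template_id: str
) -> SitePositions:
    """Read a two-column (position, expected_residue) site CSV."""
    import pandas as pd

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream)
    if not {"position", "expected_residue"} <= set(df.columns):
        raise AlignmentError("site CSV needs 'position' and 'expected_residue' columns")
    return SitePositions(
        template_id=template_id,
        positions=tuple(int(p) for p in df["position"]),
        expected_residues=tuple(str(r) for r in df["expected_residue"]),
    )


__all__ = [
    "AlignedSequences",
    "AlignmentError",
    "SitePositions",
    "percent_identity",
    "read_alignment",
    "read_sites_csv",
    "site_conservation",
    "ungapped_to_column",
]
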