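"""Toxicity-risk filtering over four ordinal risk parameters.

Fragment-based toxicity predictors report, per compound, an ordinal risk
level (none / low / high) for mutagenicity, tumorigenicity, reproductive
effect, and irritancy. The filter is strict: a compound survives only when
all four levels are *none* — even a single *low* flag excludes it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import pandas as pd


class ToxicityError(ValueError):
    """Malformed toxicity table input."""


class RiskLevel(IntEnum):
    """Ordinal predicted-risk level."""

    NONE = 0
    LOW = 1
    HIGH = 2


_LEVEL_ALIASES = {
    "no": RiskLevel.NONE,
    "none": RiskLevel.NONE,
    "low": RiskLevel.LOW,
    "high": RiskLevel.HIGH,
}

PARAMETERS = ("mutagenic", "tumorigenic", "reproductive_effective", "irritant")


def parse_level(text: str) -> RiskLevel:
    """Parse a risk level case-insensitively; 'No' and 'None' coincide."""
    key = str(text).strip().lower()
    if key not in _LEVEL_ALIASES:
        raise ToxicityError(
            f"unknown risk level {text!r}; expected one of No/None, Low, High"
        )
    return _LEVEL_ALIASES[key]


@dataclass(frozen=True)
class ToxicityProfile:
    """Four-parameter predicted risk profile for one compound."""

    compound_id: str
    mutagenic: RiskLevel
    tumorigenic: RiskLevel
    reproductive_effective: RiskLevel
    irritant: RiskLevel

    @property
    def is_risk_free(self) -> bool:
        return all(
            getattr(self, p) is RiskLevel.NONE for p in PARAMETERS
        )


def read_toxicity_table(stream: str | io.TextIOBase) -> list[ToxicityProfile]:
    """Read toxicity profiles from CSV.

    Columns: ``compound_id`` plus the four risk parameters. Unknown level
    strings raise an error naming the row and column.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    # keep_default_na=False: the literal level string "None" must not be
    # coerced to a missing value
    df = pd.read_csv(stream, dtype=str, keep_default_na=False)
    missing = ({"compound_id"} | set(PARAMETERS)) - set(df.columns)
    if missing:
        raise ToxicityError(f"toxicity CSV is missing columns: {sorted(missing)}")
    profiles: list[ToxicityProfile] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        cid = str(row["compound_id"])
        if cid in seen:
            raise ToxicityError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        levels = {}
        for param in PARAMETERS:
            try:
                levels[param] = parse_level(row[param])
            except ToxicityError as exc:
                raise ToxicityError(f"row {idx}, column {param!r}: {exc}") from exc
        profiles.append(ToxicityProfile(compound_id=cid, **levels))
    return profiles


def filter_risk_free(profiles: Sequence[ToxicityProfile]) -> list[ToxicityProfile]:
    """Keep only the profiles with no predicted risk in any category."""
    return [p for p in profiles if p.is_risk_free]


def profiles_to_frame(profiles: Sequence[ToxicityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in profiles],
            **{
                param: [getattr(p, param).name.lower() for p in profiles]
                for param in PARAMETERS
            },
        }
    )


__all__ = [
    "PARAMETERS",
    "RiskLevel",
    "ToxicityError",
    "ToxicityProfile",
    "filter_risk_free",
    "parse_level",
    "profiles_to_frame",
    "read_toxicity_table",
]
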