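"""Consensus fusion of ligand-based and structure-based probabilities.

The two screening channels are fused per compound x enzyme into a combined
probability

    Prob_Comb = (Prob_Dc + (1 + ESP) * P_Activity) / (2 + ESP)

a weighted mean of the docking probability Prob_Dc (weight 1) and the QSAR
activity probability P_Activity (weight 1 + ESP), where ESP is the QSAR
model's specificity statistic: the better the model is at rejecting
inactives, the more its probability counts. Selection is strict —
Prob_Comb > 0.5 — and a compound is *multi-target* only when selected at
every required enzyme. Compounds that fail the docking activity condition
contribute Prob_Dc = 0 rather than being dropped, which caps a pure QSAR
signal at (1 + ESP) / (2 + ESP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .docking import DockingCall

PROB_COMB_THRESHOLD = 0.5


class ConsensusError(ValueError):
    """Invalid input to a consensus operation."""


def combined_probability(prob_dc: float, p_activity: float, esp: float) -> float:
    """Fuse docking and QSAR probabilities into Prob_Comb.

    All three inputs live in [0, 1]; prob_dc = 0 encodes the not-active
    docking marker. The result is a weighted mean bounded by its two
    probability inputs, reaching 1 only when both are 1 and 0 only when
    both are 0.
    """
    for name, value in (("prob_dc", prob_dc), ("p_activity", p_activity), ("esp", esp)):
        if not 0.0 <= value <= 1.0:
            raise ConsensusError(f"{name}={value} outside [0, 1]")
    return (prob_dc + (1.0 + esp) * p_activity) / (2.0 + esp)


@dataclass(frozen=True)
class ConsensusResult:
    """Combined probability and selection flag for one compound x enzyme."""

    compound_id: str
    enzyme_id: str
    prob_dc: float
    p_activity: float
    esp: float
    prob_comb: float

    @property
    def selected(self) -> bool:
        return self.prob_comb > PROB_COMB_THRESHOLD


def consensus_results(
    calls: Iterable[DockingCall],
    p_activity: Mapping[str, float],
    esp: float,
) -> list[ConsensusResult]:
    """Combine docking calls with QSAR probabilities for one enzyme screen.

    Ligands with the not-active docking marker enter with prob_dc = 0.
    Every called compound must have a QSAR probability.
    """
    results: list[ConsensusResult] = []
    for call in calls:
        if call.compound_id not in p_activity:
            raise ConsensusError(
                f"no QSAR probability for compound {call.compound_id!r}"
            )
        prob_dc = call.prob_dc if call.prob_dc is not None else 0.0
        pa = p_activity[call.compound_id]
        results.append(
            ConsensusResult(
                compound_id=call.compound_id,
                enzyme_id=call.enzyme_id,
                prob_dc=prob_dc,
                p_activity=pa,
                esp=esp,
                prob_comb=combined_probability(prob_dc, pa, esp),
            )
        )
    return results


def select_potentially_active(results: Sequence[ConsensusResult]) -> list[ConsensusResult]:
    """Keep results with Prob_Comb strictly above 0.5, order preserved."""
    return [r for r in results if r.selected]


@dataclass(frozen=True)
class MultiTargetTable:
    """Per-compound consensus results across enzymes."""

    by_compound: Mapping[str, Mapping[str, ConsensusResult]]

    @classmethod
    def from_results(cls, results: Iterable[ConsensusResult]) -> "MultiTargetTable":
        table: dict[str, dict[str, ConsensusResult]] = {}
        for r in results:
            per_enzyme = table.setdefault(r.compound_id, {})
            if r.enzyme_id in per_enzyme:
                raise ConsensusError(
                    f"duplicate result for {r.compound_id!r} x {r.enzyme_id!r}"
                )
            per_enzyme[r.enzyme_id] = r
        return cls(by_compound=table)

    def enzymes(self) -> set[str]:
        return {e for per in self.by_compound.values() for e in per}


@dataclass(frozen=True)
class MultiTargetHit:
    """A compound selected at every required enzyme."""

    compound_id: str
    mean_prob_comb: float
    prob_comb: Mapping[str, float]


def intersect_targets(
    table: MultiTargetTable, required_enzymes: Iterable[str]
) -> list[MultiTargetHit]:
    """Compounds selected for ALL required enzymes.

    A compound missing an evaluation at a required enzyme counts as not
    selected there. Hits are ranked by mean Prob_Comb over the required
    enzymes, descending, ties broken by compound_id.
    """
    required = sorted(set(required_enzymes))
    if not required:
        raise ConsensusError("required enzyme set must not be empty")
    hits: list[MultiTargetHit] = []
    for cid, per_enzyme in table.by_compound.items():
        if all(e in per_enzyme and per_enzyme[e].selected for e in required):
            probs = {e: per_enzyme[e].prob_comb for e in required}
            hits.append(
                MultiTargetHit(
                    compound_id=cid,
                    mean_prob_comb=sum(probs.values()) / len(probs),
                    prob_comb=probs,
                )
            )
    hits.sort(key=lambda h: (-h.mean_prob_comb, h.compound_id))
    return hits


def enrichment_factor(
    ranked_ids: Sequence[str], true_actives: set[str], top_fraction: float = 0.1
) -> float:
    """Enrichment of true actives in the top fraction of a ranking.

    EF = (fraction of actives among the top ceil(f*n) compounds) /
    (prevalence of actives in the whole ranked list).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ConsensusError(f"top_fraction={top_fraction} outside (0, 1]")
    n = len(ranked_ids)
    if n == 0:
        raise ConsensusError("cannot compute enrichment of an empty ranking")
    prevalence = sum(1 for cid in ranked_ids if cid in true_actives) / n
    if prevalence == 0:
        raise ConsensusError("no true actives in the ranked list")
    n_top = max(1, int(-(-top_fraction * n // 1)))  # ceil
    top = ranked_ids[:n_top]
    top_rate = sum(1 for cid in top if cid in true_actives) / n_top
    return top_rate / prevalence


def results_to_frame(results: Sequence[ConsensusResult]) -> pd.DataFrame:
    """Tabulate consensus results (Prob values rounded to 4 dp)."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "enzyme_id": [r.enzyme_id for r in results],
            "prob_dc": [round(r.prob_dc, 4) for r in results],
            "p_activity": [round(r.p_activity, 4) for r in results],
            "esp": [round(r.esp, 4) for r in results],
            "prob_comb": [round(r.prob_comb, 4) for r in results],
            "selected": [int(r.selected) for r in results],
        }
    )


def hits_to_json(hits: Sequence[MultiTargetHit]) -> str:
    payload = [
        {
            "compound_id": h.compound_id,
            "mean_prob_comb": round(h.mean_prob_comb, 4),
            "prob_comb": {e: round(p, 4) for e, p in h.prob_comb.items()},
        }
        for h in hits
    ]
    return json.dumps(payload, indent=2)


__all__ = [
    "PROB_COMB_THRESHOLD",
    "ConsensusError",
    "ConsensusResult",
    "MultiTargetHit",
    "MultiTargetTable",
    "combined_probability",
    "consensus_results",
    "enrichment_factor",
    "hits_to_json",
    "intersect_targets",
    "results_to_frame",
    "select_potentially_active",
]
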