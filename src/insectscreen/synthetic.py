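"""Seeded synthetic inputs with the statistical structure the screen assumes.

Every stage of the pipeline is testable offline: the generators emit (a) a
labelled compound library whose descriptor matrix carries a class-mean
shift of ``effect_size`` descriptor standard deviations in a random
informative column subset, (b) per-enzyme docking tables whose energies are
coupled to the planted activity signal, and (c) toxicity profiles that are
all-clean at a given rate.

Descriptor columns are generic Gaussian features named in three blocks
(``getaway_*``, ``whim_*``, ``rdf_*``) to mirror the 3D descriptor families
a real campaign would use; no actual descriptor semantics are claimed.
Docking energies are drawn on the MolDock magnitude scale (baseline -150,
roughly -250 to -50 kcal/mol-scaled units) so generated tables look like
real screening output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curation import CompoundRecord, Label, LabeledCompound
from .qsar import DescriptorMatrix
from .docking import DockingScoreTable
from .toxicity import PARAMETERS, RiskLevel, ToxicityProfile

DEFAULT_ENZYMES = ("ache", "nachr", "cht")
DOCKING_BASELINE = -150.0
INFORMATIVE_FRACTION = 0.3


class SyntheticSpecError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class LibrarySpec:
    """Synthetic compound-library specification.

    ``active_fraction`` defaults to 91/166, the class balance of a typical
    curated insecticidal-activity modelling set; ``effect_size`` is the
    active-vs-inactive descriptor mean shift in units of the descriptor
    standard deviation.
    """

    n_compounds: int
    n_descriptors: int = 30
    active_fraction: float = 91 / 166
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 4:
            raise SyntheticSpecError("n_compounds must be >= 4")
        if self.n_descriptors < 1:
            raise SyntheticSpecError("n_descriptors must be >= 1")
        if not 0.0 < self.active_fraction < 1.0:
            raise SyntheticSpecError("active_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise SyntheticSpecError("effect_size must be >= 0")
        n_active = round(self.active_fraction * self.n_compounds)
        if n_active < 1 or n_active > self.n_compounds - 1:
            raise SyntheticSpecError("spec leaves a class empty after rounding")


@dataclass(frozen=True)
class LibraryTruth:
    """Planted ground truth behind a generated library."""

    active_ids: frozenset[str]
    informative_indices: tuple[int, ...]
    activity_signal: Mapping[str, float]


def _descriptor_names(n: int) -> tuple[str, ...]:
    blocks = ("getaway", "whim", "rdf")
    return tuple(f"{blocks[i % 3]}_{i // 3 + 1}" for i in range(n))


def generate_library(
    spec: LibrarySpec,
    informative_indices: Sequence[int] | None = None,
) -> tuple[list[LabeledCompound], DescriptorMatrix, LibraryTruth]:
    """Generate a labelled library with class-separable descriptors.

    Actives draw pLC50 uniformly in [4.5, 7.5), inactives in [2.0, 4.5).
    Descriptors are standard normal; actives are shifted by ``effect_size``
    in the informative columns (a random 30% subset, or the indices passed
    in, which lets a second bank share the signal geometry of a first).
    Identical spec and seed give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_active = round(spec.active_fraction * n)
    labels = np.array([1] * n_active + [0] * (n - n_active))
    rng.shuffle(labels)
    ids = tuple(f"C{i + 1:04d}" for i in range(n))

    plc50 = np.where(
        labels == 1,
        rng.uniform(4.5, 7.5, size=n),
        rng.uniform(2.0, 4.5, size=n),
    )

    if informative_indices is None:
        n_inf = max(1, round(INFORMATIVE_FRACTION * spec.n_descriptors))
        informative = tuple(
            sorted(rng.choice(spec.n_descriptors, size=n_inf, replace=False).tolist())
        )
    else:
        informative = tuple(sorted(int(i) for i in informative_indices))
        if any(i < 0 or i >= spec.n_descriptors for i in informative):
            raise SyntheticSpecError("informative index out of descriptor range")

    values = rng.standard_normal((n, spec.n_descriptors))
    values[np.ix_(labels == 1, list(informative))] += spec.effect_size

    labeled = [
        LabeledCompound(
            record=CompoundRecord(compound_id=cid, plc50=float(p)),
            label=Label.ACTIVE if lab == 1 else Label.INACTIVE,
        )
        for cid, p, lab in zip(ids, plc50, labels)
    ]
    matrix = DescriptorMatrix(
        compound_ids=ids,
        descriptor_names=_descriptor_names(spec.n_descriptors),
        values=values,
    )
    truth = LibraryTruth(
        active_ids=frozenset(cid for cid, lab in zip(ids, labels) if lab == 1),
        informative_indices=informative,
        activity_signal={cid: float(lab) for cid, lab in zip(ids, labels)},
    )
    return labeled, matrix, truth


@dataclass(frozen=True)
class DockingSpec:
    """Synthetic docking-table specification.

    ``coupling`` is the mean energy decrease (score units) per unit of the
    planted activity signal; ``reference_quantile`` places the reference
    inhibitor's energy within the generated score distribution (0.75 means
    the reference binds more weakly than 75% of the ligands, so those 75%
    pass the activity condition).
    """

    enzyme_ids: tuple[str, ...] = DEFAULT_ENZYMES
    coupling: float = 10.0
    noise_sd: float = 5.0
    reference_quantile: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.enzyme_ids:
            raise SyntheticSpecError("at least one enzyme is required")
        if self.coupling < 0 or self.noise_sd < 0:
            raise SyntheticSpecError("coupling and noise_sd must be >= 0")
        if not 0.0 < self.reference_quantile < 1.0:
            raise SyntheticSpecError("reference_quantile must lie in (0, 1)")


def generate_docking_tables(
    truth: LibraryTruth, spec: DockingSpec
) -> dict[str, DockingScoreTable]:
    """Generate per-enzyme docking tables coupled to the planted signal.

    score = baseline - coupling * activity_signal + N(0, noise_sd), clipped
    to stay strictly negative; the reference inhibitor energy sits at the
    stated quantile of the generated scores. Heavy-atom counts are drawn
    uniformly in [15, 40].
    """
    ids = sorted(truth.activity_signal)
    signal = np.array([truth.activity_signal[cid] for cid in ids])
    tables: dict[str, DockingScoreTable] = {}
    for idx, enzyme in enumerate(spec.enzyme_ids):
        rng = np.random.default_rng([spec.seed, idx])
        scores = (
            DOCKING_BASELINE
            - spec.coupling * signal
            + rng.normal(0.0, spec.noise_sd, size=len(ids))
        )
        scores = np.minimum(scores, -1.0)
        reference = float(np.quantile(scores, spec.reference_quantile))
        heavy = rng.integers(15, 41, size=len(ids))
        tables[enzyme] = DockingScoreTable(
            enzyme_id=enzyme,
            ligand_scores=dict(zip(ids, scores.tolist())),
            reference_inhibitor_score=reference,
            reference_id="insecticide",
            heavy_atoms=dict(zip(ids, (int(h) for h in heavy))),
        )
    return tables


def generate_toxicity(
    compound_ids: Sequence[str], clean_rate: float, seed: int = 0
) -> list[ToxicityProfile]:
    """Generate four-parameter toxicity profiles at a given clean rate.

    Each compound is all-none with probability ``clean_rate``; otherwise at
    least one parameter is flagged low or high.
    """
    if not 0.0 <= clean_rate <= 1.0:
        raise SyntheticSpecError("clean_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    profiles: list[ToxicityProfile] = []
    for cid in compound_ids:
        levels = {param: RiskLevel.NONE for param in PARAMETERS}
        if rng.random() >= clean_rate:
            n_flagged = int(rng.integers(1, len(PARAMETERS) + 1))
            flagged = rng.choice(len(PARAMETERS), size=n_flagged, replace=False)
            for i in flagged:
                levels[PARAMETERS[i]] = (
                    RiskLevel.LOW if rng.random() < 0.5 else RiskLevel.HIGH
                )
        profiles.append(ToxicityProfile(compound_id=str(cid), **levels))
    return profiles


__all__ = [
    "DEFAULT_ENZYMES",
    "DOCKING_BASELINE",
    "DockingSpec",
    "LibrarySpec",
    "LibraryTruth",
    "SyntheticSpecError",
    "generate_docking_tables",
    "generate_library",
    "generate_toxicity",
]
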