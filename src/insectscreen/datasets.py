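"""Bundled worked-example datasets.

Small reference tables for the two screening campaigns the package is built
around: the 15 multi-target diterpene candidates against the cotton aphid
(*Aphis gossypii*) and the 37 against the fruit fly (*Drosophila
melanogaster*), each screened at three insect enzymes (acetylcholinesterase
``ache``, nicotinic acetylcholine receptor ``nachr``, chitinase ``cht``).

Per species the bundle carries:

* docking scores (MolDock-style primary, GoldScore-style secondary) with
  the reference insecticide row per enzyme,
* the reported combined consensus probabilities and QSAR activity
  probabilities for the candidate compounds,
* four-parameter toxicity risk profiles,
* plus the random-forest model performance summary and the curated
  modelling-set class sizes.

The consensus probabilities are carried as data: they were produced against
the full ~2000-compound screening bank, whose docking scores are not
shipped, so they cannot be recomputed from the candidate subset alone.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .docking import DockingScoreTable, read_docking_tables
from .toxicity import ToxicityProfile, read_toxicity_table

APHIS_ENZYMES = ("ache", "nachr", "cht")
DROSO_ENZYMES = ("ache", "nachr")


def _read_text(name: str) -> str:
    return resources.files("insectscreen.data").joinpath(name).read_text()


def load_docking_tables(species: str) -> dict[str, DockingScoreTable]:
    """Per-enzyme docking tables for ``aphis`` or ``drosophila``."""
    prefix = _prefix(species)
    return read_docking_tables(_read_text(f"{prefix}_multitarget_docking.csv"))


def load_consensus_table(species: str) -> pd.DataFrame:
    """Reported Prob_Comb and P_Activity per compound x enzyme."""
    prefix = _prefix(species)
    return pd.read_csv(
        resources.files("insectscreen.data").joinpath(
            f"{prefix}_multitarget_consensus.csv"
        ),
        dtype={"compound_id": str},
    )


def load_toxicity_profiles(species: str) -> list[ToxicityProfile]:
    """Four-parameter toxicity risk profiles for the candidate compounds."""
    prefix = _prefix(species)
    return read_toxicity_table(_read_text(f"{prefix}_multitarget_toxicity.csv"))


def load_rf_performance() -> pd.DataFrame:
    """Random-forest model performance (test and cross-validation rows)."""
    return pd.read_csv(resources.files("insectscreen.data").joinpath("rf_performance.csv"))


def load_modeling_set_sizes() -> pd.DataFrame:
    """Curated modelling-set class sizes per species."""
    return pd.read_csv(
        resources.files("insectscreen.data").joinpath("modeling_set_sizes.csv")
    )


def required_enzymes(species: str) -> tuple[str, ...]:
    """Enzymes a compound must hit to count as multi-target per species."""
    return APHIS_ENZYMES if _prefix(species) == "aphis" else DROSO_ENZYMES


def _prefix(species: str) -> str:
    key = species.lower()
    if key in {"aphis", "a. gossypii", "aphis_gossypii"}:
        return "aphis"
    if key in {"droso", "drosophila", "d. melanogaster", "drosophila_melanogaster"}:
        return "droso"
    raise ValueError(f"unknown species {species!r}; use 'aphis' or 'drosophila'")


__all__ = [
    "APHIS_ENZYMES",
    "DROSO_ENZYMES",
    "load_consensus_table",
    "load_docking_tables",
    "load_modeling_set_sizes",
    "load_rf_performance",
    "load_toxicity_profiles",
    "required_enzymes",
]
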