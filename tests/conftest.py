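"""Shared fixtures: tiny in-memory libraries and alignments."""

from __future__ import annotations

import pytest

from insectscreen import synthetic
from insectscreen.curation import CompoundRecord


@pytest.fixture
def small_library_csv() -> str:
    return (
        "compound_id,smiles,plc50,species_tag\n"
        "cpd1,CCO,5.1,aphis\n"
        "cpd2,c1ccccc1,4.5,aphis\n"
        "cpd3,CC(=O)O,4.4999,aphis\n"
        "cpd4,,3.2,drosophila\n"
    )


@pytest.fixture
def three_molecule_sdf() -> str:
    """Three V2000 records built with RDKit, pLC50 in a data field."""
    from rdkit import Chem

    blocks = []
    for name, smi, plc in [("m1", "CCO", 5.0), ("m2", "CCN", 4.2), ("m3", "CCC", 6.1)]:
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", name)
        mol.SetProp("pLC50", str(plc))
        blocks.append(Chem.MolToMolBlock(mol) + f">  <pLC50>\n{plc}\n\n$$$$\n")
    return "".join(blocks)


@pytest.fixture
def toy_alignment_fasta() -> str:
    return (
        ">template\nACDG-KWYH\n"
        ">query_close\nACEG-KWYH\n"
        ">query_far\nQQQQ-QQQQ\n"
    )


def make_records(plc50s: list[float]) -> list[CompoundRecord]:
    return [
        CompoundRecord(compound_id=f"c{i}", plc50=p) for i, p in enumerate(plc50s)
    ]


@pytest.fixture
def strong_signal_library():
    """Well-separated 200-compound library (3 sigma descriptor shift)."""
    spec = synthetic.LibrarySpec(n_compounds=200, effect_size=3.0, seed=7)
    return synthetic.generate_library(spec)
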