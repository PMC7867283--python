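"""Docking table ingestion and energy-ratio probability normalization."""

import numpy as np
import pytest

from insectscreen import datasets, docking
from insectscreen.docking import (
    DockingScoreTable,
    DockingTableError,
    call_actives,
    docking_probability,
    ligand_efficiency,
)


def make_table(scores: dict[str, float], reference: float, enzyme="ache") -> DockingScoreTable:
    return DockingScoreTable(
        enzyme_id=enzyme, ligand_scores=scores, reference_inhibitor_score=reference
    )


class TestReadDockingTables:
    def test_bundled_aphis_campaign(self):
        tables = datasets.load_docking_tables("aphis")
        assert set(tables) == {"ache", "nachr", "cht"}
        for table in tables.values():
            assert len(table.ligand_scores) == 15
        assert tables["ache"].reference_inhibitor_score == pytest.approx(-88.38)
        assert tables["ache"].reference_id == "chlorpyrifos"

    def test_empty_ligand_section_allowed(self):
        csv = "compound_id,enzyme_id,score,is_reference\nref,ache,-88.4,1\n"
        table = docking.read_docking_table(csv)
        assert table.ligand_scores == {}

    def test_duplicate_reference_rejected(self):
        csv = (
            "compound_id,enzyme_id,score,is_reference\n"
            "r1,ache,-88.4,1\nr2,ache,-90.0,1\n"
        )
        with pytest.raises(DockingTableError, match="more than one reference"):
            docking.read_docking_table(csv)

    def test_missing_reference_rejected(self):
        csv = "compound_id,enzyme_id,score,is_reference\nlig,ache,-100.0,0\n"
        with pytest.raises(DockingTableError, match="no reference"):
            docking.read_docking_table(csv)

    def test_non_numeric_score_names_the_row(self):
        csv = (
            "compound_id,enzyme_id,score,is_reference\n"
            "lig,ache,strong,0\nref,ache,-88.4,1\n"
        )
        with pytest.raises(DockingTableError, match="lig"):
            docking.read_docking_table(csv)

    def test_round_trip_through_csv(self):
        tables = datasets.load_docking_tables("drosophila")
        text = docking.write_docking_tables_csv(tables)
        back = docking.read_docking_tables(text)
        assert set(back) == set(tables)
        for enzyme in tables:
            assert back[enzyme].ligand_scores == pytest.approx(tables[enzyme].ligand_scores)


class TestDockingProbability:
    def test_energy_ratio_of_reported_candidates(self):
        # second-best AChE binder over the best, both beating the insecticide
        assert docking_probability(-217.92, -223.77, -88.38) == pytest.approx(
            0.9739, abs=5e-5
        )

    def test_best_ligand_has_probability_one(self):
        assert docking_probability(-223.77, -223.77, -88.38) == 1.0

    def test_weaker_than_reference_is_not_active(self):
        assert docking_probability(-80.0, -223.77, -88.38) is docking.NOT_ACTIVE

    def test_validation(self):
        with pytest.raises(DockingTableError, match="non-zero"):
            docking_probability(-10.0, 0.0, -5.0)
        with pytest.raises(DockingTableError, match="negative"):
            docking_probability(10.0, -223.77, -88.38)
        with pytest.raises(DockingTableError, match="minimum"):
            docking_probability(-300.0, -223.77, -88.38)

    def test_monotone_in_ligand_energy(self):
        e_mlig, e_inib = -200.0, -50.0
        probs = [docking_probability(e, e_mlig, e_inib) for e in (-199.0, -150.0, -100.0)]
        assert probs == sorted(probs, reverse=True)
        assert all(0 < p < 1 for p in probs)


class TestCallActives:
    def test_every_reported_candidate_beats_its_reference(self):
        # each compound with a reported combined probability passes the
        # energy condition at that enzyme, for both campaigns
        for species in ("aphis", "drosophila"):
            tables = datasets.load_docking_tables(species)
            consensus = datasets.load_consensus_table(species)
            active = {
                (c.compound_id, c.enzyme_id)
                for t in tables.values()
                for c in call_actives(t)
                if c.is_potentially_active
            }
            for row in consensus.itertuples(index=False):
                assert (str(row.compound_id), row.enzyme_id) in active

    def test_all_above_reference_gives_zero_actives(self):
        table = make_table({"a": -40.0, "b": -50.0}, reference=-60.0)
        calls = call_actives(table)
        assert sum(c.is_potentially_active for c in calls) == 0
        assert all(c.prob_dc is None for c in calls)

    def test_single_ligand_is_its_own_minimum(self):
        (call,) = call_actives(make_table({"only": -100.0}, reference=-60.0))
        assert call.prob_dc == 1.0

    def test_order_invariance_and_rescaling(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            scores = {f"l{i}": float(-rng.uniform(50, 250)) for i in range(n)}
            ref = float(-rng.uniform(40, 260))
            table = make_table(scores, ref)
            shuffled = make_table(
                {k: scores[k] for k in rng.permutation(list(scores))}, ref
            )
            probs = {c.compound_id: c.prob_dc for c in call_actives(table)}
            probs_shuffled = {c.compound_id: c.prob_dc for c in call_actives(shuffled)}
            assert probs == probs_shuffled
            # brute-force recomputation
            e_mlig = min(scores.values())
            for cid, score in scores.items():
                expected = score / e_mlig if score < ref else None
                assert probs[cid] == (pytest.approx(expected) if expected else expected)
            # a new strictly-better ligand rescales every probability downward
            better = e_mlig - 10.0
            bigger = make_table({**scores, "new_best": better}, ref)
            probs2 = {c.compound_id: c.prob_dc for c in call_actives(bigger)}
            for cid in scores:
                if probs[cid] is not None and probs2[cid] is not None:
                    assert probs2[cid] < probs[cid]

    def test_probability_one_only_at_minimum(self):
        table = make_table({"best": -200.0, "other": -150.0}, reference=-50.0)
        probs = {c.compound_id: c.prob_dc for c in call_actives(table)}
        assert probs["best"] == 1.0
        assert 0 < probs["other"] < 1

    def test_empty_table_rejected(self):
        with pytest.raises(DockingTableError, match="empty"):
            call_actives(make_table({}, reference=-60.0))


class TestLigandEfficiency:
    @pytest.mark.parametrize(
        "score,atoms,expected",
        [(-100.0, 20, -5.0), (-88.38, 17, -5.20), (0.0, 7, 0.0)],
    )
    def test_score_per_heavy_atom(self, score, atoms, expected):
        assert ligand_efficiency(score, atoms) == pytest.approx(expected, abs=5e-3)

    def test_heavy_atom_count_must_be_positive(self):
        with pytest.raises(DockingTableError, match="heavy_atoms"):
            ligand_efficiency(-100.0, 0)
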