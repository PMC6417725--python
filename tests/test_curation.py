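"""Curation rules: labelling, structure filters, deduplication, invariants."""

import pandas as pd
import pytest
from rdkit import Chem

from rationalqsar.curation import (
    CurationStatus,
    Label,
    assign_activity_label,
    canonicalize_smiles,
    check_elements,
    curate,
    desalt_and_neutralize,
    filter_mixture_and_low_carbon,
)


@pytest.mark.parametrize(
    "primary, confirm, counter, expected",
    [
        (40, 55, 0, Label.ACTIVE),          # confirmed, counterscreen-clean
        (0, None, None, Label.INACTIVE),    # primary screen negative
        (40, 55, 30, Label.INCONCLUSIVE),   # luciferase interferer
        (40, 5, 0, Label.INCONCLUSIVE),     # confirmatory score below 10
        (40, None, None, Label.INCONCLUSIVE),  # primary hit never retested
        (None, None, None, Label.INCONCLUSIVE),  # untested
        (50, 10, 0, Label.ACTIVE),          # confirmatory boundary inclusive
        (50, 100, 0, Label.ACTIVE),
    ],
)
def test_activity_labelling(primary, confirm, counter, expected):
    assert assign_activity_label(primary, confirm, counter) is expected


def test_score_out_of_range_names_the_field():
    with pytest.raises(ValueError, match="confirm_score"):
        assign_activity_label(40, 101, 0)


@pytest.mark.parametrize(
    "smiles, keep, element",
    [
        ("c1ccccc1", True, None),
        ("CC[Se]CC", False, "Se"),
        ("[Fe+2].[O-]C(=O)C", False, "Fe"),
        ("CC(=O)[O-].[Na+]", True, None),  # Na is whitelisted
    ],
)
def test_element_whitelist(smiles, keep, element):
    result, offending = check_elements(Chem.MolFromSmiles(smiles, sanitize=False))
    assert result is keep
    assert offending == element


def test_desalt_neutralizes_carboxylate_salt():
    components = desalt_and_neutralize(Chem.MolFromSmiles("CC(=O)[O-].[Na+]"))
    organics = [Chem.MolToSmiles(m) for m, org in components if org]
    inorganics = [m for m, org in components if not org]
    assert organics == ["CC(=O)O"]
    assert len(inorganics) == 1


def test_desalt_identity_on_neutral_molecule():
    components = desalt_and_neutralize(Chem.MolFromSmiles("c1ccccc1"))
    assert len(components) == 1
    assert Chem.MolToSmiles(components[0][0]) == "c1ccccc1"


def test_quaternary_ammonium_not_neutralizable():
    assert desalt_and_neutralize(Chem.MolFromSmiles("C[N+](C)(C)C.[Cl-]")) is None


def test_protonated_amine_is_deprotonated():
    components = desalt_and_neutralize(Chem.MolFromSmiles("CC[NH3+].[Cl-]"))
    assert components is not None
    organics = [Chem.MolToSmiles(m) for m, org in components if org]
    assert organics == ["CCN"]


@pytest.mark.parametrize(
    "smiles, expected_reason",
    [
        ("CCO.CCN", CurationStatus.REMOVED_MIXTURE),
        ("C", CurationStatus.REMOVED_LOW_CARBON),
        ("O=S(=O)(O)O", CurationStatus.REMOVED_LOW_CARBON),  # zero organic components
        ("CCO", None),
    ],
)
def test_mixture_and_low_carbon_filter(smiles, expected_reason):
    components = desalt_and_neutralize(Chem.MolFromSmiles(smiles))
    parent, reason = filter_mixture_and_low_carbon(components)
    assert reason is expected_reason
    assert (parent is None) == (expected_reason is not None)


@pytest.mark.parametrize("a, b", [("OCC", "CCO"), ("c1ccccc1", "C1=CC=CC=C1")])
def test_canonicalization_is_graph_invariant(a, b):
    assert canonicalize_smiles(a) == canonicalize_smiles(b)


def test_canonicalization_is_idempotent():
    once = canonicalize_smiles("C1=CC=CC=C1CCO")
    assert canonicalize_smiles(once) == once


def _toy_table():
    # one Se structure, one salt, one mixture, one methane, two identical concordant
    return pd.DataFrame(
        {
            "id": ["se", "salt", "mix", "meth", "dup1", "dup2"],
            "smiles": ["CC[Se]CC", "CC(=O)[O-].[Na+]", "CCO.CCN", "C",
                       "c1ccccc1CCO", "OCCc1ccccc1"],
            "score_primary": [0, 0, 0, 0, 40, 40],
            "score_confirm": [None, None, None, None, 55, 55],
            "score_counter": [None, None, None, None, 0, 0],
        }
    )


def test_curate_toy_table_traces_each_rule():
    dataset = curate(_toy_table())
    counts = dataset.removal_counts()
    assert counts["KEPT"] == 2  # the salt parent + one of the duplicate pair
    assert counts["REMOVED_ELEMENT"] == 1
    assert counts["REMOVED_MIXTURE"] == 1
    assert counts["REMOVED_LOW_CARBON"] == 1
    assert counts["MERGED_DUPLICATE"] == 1
    status = {r.id: r.curation_status for r in dataset.records}
    assert status["se"] is CurationStatus.REMOVED_ELEMENT
    assert status["salt"] is CurationStatus.KEPT
    assert {status["dup1"], status["dup2"]} == {
        CurationStatus.KEPT, CurationStatus.MERGED_DUPLICATE
    }


def test_conflicting_duplicates_remove_whole_group():
    table = pd.DataFrame(
        {
            "id": ["x", "y"],
            "smiles": ["c1ccccc1CCO", "OCCc1ccccc1"],
            "score_primary": [40, 0],
            "score_confirm": [55, None],
            "score_counter": [0, None],
        }
    )
    dataset = curate(table)
    assert all(
        r.curation_status is CurationStatus.REMOVED_DUPLICATE_CONFLICT
        for r in dataset.records
    )
    assert all(r.canonical_smiles is None for r in dataset.records)


def test_inconclusive_plus_conclusive_duplicate_keeps_conclusive():
    table = pd.DataFrame(
        {
            "id": ["inc", "act"],
            "smiles": ["c1ccccc1CCO", "OCCc1ccccc1"],
            "score_primary": [40, 40],
            "score_confirm": [55, 60],
            "score_counter": [30, 0],  # first is a luciferase interferer
        }
    )
    kept = curate(table).kept
    assert len(kept) == 1
    assert kept[0].label is Label.ACTIVE
    assert kept[0].id == "act"


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        curate(pd.DataFrame(columns=["id", "smiles"]))


def test_curation_invariants_on_contaminated_fixture(contaminated_table):
    """Idempotence, uniqueness, conservation and label consistency."""
    table, _ = contaminated_table
    dataset = curate(table)

    # conservation: every input accounted for exactly once
    counts = dataset.removal_counts()
    assert sum(counts.values()) == len(table)

    # uniqueness: kept canonical SMILES pairwise distinct
    kept = dataset.kept
    canon = [r.canonical_smiles for r in kept]
    assert len(canon) == len(set(canon))

    # label function: stored label rederivable from stored scores
    for r in kept:
        assert r.label is assign_activity_label(
            r.primary_score, r.confirm_score, r.counter_score
        )

    # idempotence: re-curating the kept output changes nothing
    kept_frame = dataset.kept_frame().rename(columns={"canonical_smiles": "smiles"})
    scores = {r.id: (r.primary_score, r.confirm_score, r.counter_score) for r in kept}
    kept_frame["score_primary"] = [scores[i][0] for i in kept_frame["id"]]
    kept_frame["score_confirm"] = [scores[i][1] for i in kept_frame["id"]]
    kept_frame["score_counter"] = [scores[i][2] for i in kept_frame["id"]]
    again = curate(kept_frame.drop(columns=["label"]))
    assert len(again.kept) == len(kept)
    assert sorted(r.canonical_smiles for r in again.kept) == sorted(canon)


def test_contaminant_ground_truth_statuses(contaminated_table):
    """Injected contaminants end in their tagged curation status."""
    table, _ = contaminated_table
    dataset = curate(table)
    status = {r.id: r.curation_status.value for r in dataset.records}
    checked = 0
    for row in table.itertuples(index=False):
        if row.expected_status in (
            "REMOVED_MIXTURE", "REMOVED_LOW_CARBON", "REMOVED_ELEMENT",
            "REMOVED_DUPLICATE_CONFLICT",
        ):
            assert status[row.id] == row.expected_status, row.id
            checked += 1
        elif row.expected_status == "MERGED_DUPLICATE":
            assert status[row.id] in ("MERGED_DUPLICATE", "KEPT"), row.id
            checked += 1
    assert checked > 0
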