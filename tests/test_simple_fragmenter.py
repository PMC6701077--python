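"""The heuristic fragmenter: worked molecules, series, and invariants."""

import pytest

from unifrag import fragment_simple, normalize_structure
from unifrag.engine import AssignmentState, Status, find_match_candidates
from unifrag.fixtures import generate_series
from unifrag.simple_fragmenter import parent_first_search

from conftest import names


@pytest.mark.parametrize("smiles,expected", [
    ("O", {"H2O": 1}),
    ("CO", {"CH3OH": 1}),
    ("CCCC", {"CH3": 2, "CH2": 2}),
    ("c1c(Cl)c([OH])ccc1", {"ACOH": 1, "ACCl": 1, "ACH": 4}),
    ("Cc1ccccc1", {"ACCH3": 1, "ACH": 5}),
    ("CC(=O)NC", {"CONHCH3": 1, "CH3": 1}),          # amide protected from CH3/CH3NH
    ("CCOC(C)=O", {"CH3COO": 1, "CH2": 1, "CH3": 1}),  # ethyl acetate
    ("c1ccncc1", {"C5H5N": 1}),                       # pyridine as one group
])
def test_known_fragmentations(scheme, smiles, expected):
    result = fragment_simple(normalize_structure(smiles), scheme)
    assert result.status is Status.SUCCESS
    assert names(scheme, result.group_counts) == expected


def test_uncoverable_molecule_reports_no_solution(scheme):
    result = fragment_simple(normalize_structure("C1=CN=CC#C1"), scheme)
    assert result.status is Status.NO_SOLUTION
    assert result.fragmentation is None


def test_success_iff_full_partition(scheme):
    for smiles in ["CCO", "Cc1ccccc1", "CC(C)(C)O", "C1CCOC1"]:
        result = fragment_simple(normalize_structure(smiles), scheme)
        assert result.status is Status.SUCCESS
        mol = normalize_structure(smiles)
        covered = [a for c in result.fragmentation.candidates for a in c.atom_ids]
        assert sorted(covered) == list(range(mol.n_heavy))


@pytest.mark.parametrize("family,start", [
    ("n-alkane", 2), ("1-alkanol", 2), ("chloroalkane", 2), ("alkylbenzene", 1),
])
def test_homologous_series_closed_forms(scheme, family, start):
    for smiles, expected in generate_series(family, start, 11):
        result = fragment_simple(normalize_structure(smiles), scheme)
        assert result.status is Status.SUCCESS, smiles
        assert dict(result.group_counts) == dict(expected), smiles


def test_determinism(scheme):
    smiles = "CC(C)Cc1ccc(O)cc1"
    runs = [fragment_simple(normalize_structure(smiles), scheme) for _ in range(3)]
    parts = {r.fragmentation.atom_partition() for r in runs}
    assert len(parts) == 1


def test_unsorted_scan_falls_into_reference_unlike_cover(scheme):
    """Without descriptor sorting the file-order scan eats the aromatic
    ring before the chlorine; only the clearing/adjacency retries rescue
    chlorophenol, and they land on the split AC+OH assignment instead of
    the reference ACOH one."""
    unsorted_result = fragment_simple(normalize_structure("c1c(Cl)c([OH])ccc1"),
                                      scheme, sorted_patterns=False)
    assert unsorted_result.status is Status.SUCCESS
    assert unsorted_result.iterations_used > 0
    assert names(scheme, unsorted_result.group_counts) == \
           {"ACH": 4, "ACCl": 1, "AC": 1, "OH": 1}


class TestParentFirstSearch:
    def test_child_suppressed_inside_intact_parent_site(self, scheme):
        # N-methylacetamide: CH3-C(=O)-NH-CH3; CONHCH3 parent protects CH3
        mol = normalize_structure("CC(=O)NC")
        state = AssignmentState(mol)
        cands = parent_first_search(mol, scheme.group(1), scheme, state)
        # both methyls sit inside intact amide-parent matches
        assert cands == []

    def test_group_without_parents_unaffected(self, scheme):
        mol = normalize_structure("O")
        state = AssignmentState(mol)
        cands = parent_first_search(mol, scheme.group(16), scheme, state)
        assert [set(c.atom_ids) for c in cands] == [{0}]

    def test_suppression_lifts_when_parent_blocked(self, scheme):
        # place the carbonyl's oxygen-neighbour region so no amide parent
        # match survives intact; the methyl becomes available again
        mol = normalize_structure("CC(=O)NC")
        state = AssignmentState(mol)
        conhch3 = find_match_candidates(mol, scheme.group(95))[0]
        state.place(conhch3)
        cands = parent_first_search(mol, scheme.group(1), scheme, state)
        assert [set(c.atom_ids) for c in cands] == [{0}]
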