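"""Normalization, match enumeration, adjacency and assignment state."""

import pytest

from unifrag import normalize_structure
from unifrag.engine import (
    AssignmentState,
    ExclusionRejection,
    ParseRejection,
    clear_neighborhood,
    find_match_candidates,
    is_adjacent,
)


class TestNormalization:
    def test_deuterated_water_becomes_water(self):
        mol = normalize_structure("[2H]O[2H]")
        assert mol.n_heavy == 1
        assert mol.rdmol.GetAtomWithIdx(0).GetSymbol() == "O"
        assert mol.rdmol.GetAtomWithIdx(0).GetTotalNumHs() == 2

    def test_plain_molecule(self):
        assert normalize_structure("CC").n_heavy == 2

    def test_salt_is_excluded(self):
        with pytest.raises(ExclusionRejection) as exc:
            normalize_structure("[Na+].[Cl-]")
        assert exc.value.reason == "salt"

    def test_radical_is_excluded(self):
        with pytest.raises(ExclusionRejection) as exc:
            normalize_structure("[CH3]")
        assert exc.value.reason == "radical"

    def test_garbage_is_a_parse_rejection(self):
        with pytest.raises(ParseRejection):
            normalize_structure("not-a-smiles(((")


class TestMatchCandidates:
    def test_butane_methyls(self, scheme):
        mol = normalize_structure("CCCC")
        cands = find_match_candidates(mol, scheme.group(1))
        assert [set(c.atom_ids) for c in cands] == [{0}, {3}]

    def test_benzene_aromatic_ch(self, scheme):
        mol = normalize_structure("c1ccccc1")
        cands = find_match_candidates(mol, scheme.group(9))
        assert len(cands) == 6
        assert all(len(c.atom_ids) == 1 for c in cands)

    def test_no_match_gives_empty_list(self, scheme):
        assert find_match_candidates(normalize_structure("O"), scheme.group(1)) == []

    def test_order_is_deterministic(self, scheme):
        mol = normalize_structure("CC(C)Cc1ccccc1")
        ref = find_match_candidates(mol, scheme.group(2))
        for _ in range(3):
            again = find_match_candidates(normalize_structure("CC(C)Cc1ccccc1"),
                                          scheme.group(2))
            assert again == ref


class TestAssignmentState:
    def _place(self, scheme, smiles, group_id, which=0):
        mol = normalize_structure(smiles)
        state = AssignmentState(mol)
        cand = find_match_candidates(mol, scheme.group(group_id))[which]
        state.place(cand)
        return mol, state

    def test_non_overlap_enforced(self, scheme):
        mol, state = self._place(scheme, "CCCC", 1)
        cand = find_match_candidates(mol, scheme.group(1))[0]
        with pytest.raises(ValueError):
            state.place(cand)

    def test_adjacency(self, scheme):
        mol, state = self._place(scheme, "CCCC", 1, which=0)  # atom 0
        ch2 = find_match_candidates(mol, scheme.group(2))
        near = next(c for c in ch2 if c.atom_ids == {1})
        far_ch3 = find_match_candidates(mol, scheme.group(1))[1]  # atom 3
        assert is_adjacent(near, state, mol)
        assert not is_adjacent(far_ch3, state, mol)

    def test_empty_state_is_adjacent_to_anything(self, scheme):
        mol = normalize_structure("CCCC")
        state = AssignmentState(mol)
        cand = find_match_candidates(mol, scheme.group(1))[0]
        assert is_adjacent(cand, state, mol)

    def test_clear_neighborhood_radius_one(self, scheme):
        # pentane with both CH3 placed: only the CH3 near the middle gap goes
        mol = normalize_structure("CCCCC")
        state = AssignmentState(mol)
        for c in find_match_candidates(mol, scheme.group(1)):
            state.place(c)
        ch2 = find_match_candidates(mol, scheme.group(2))
        state.place(next(c for c in ch2 if c.atom_ids == {1}))
        # unassigned: atoms 2, 3; radius 1 clears {1}, {3}-adjacent groups
        clear_neighborhood(state, mol, 1)
        assert {frozenset(c.atom_ids) for c in state.placed} == {frozenset({0})}

    def test_clear_beyond_diameter_empties_state(self, scheme):
        mol = normalize_structure("CCCC")
        state = AssignmentState(mol)
        state.place(find_match_candidates(mol, scheme.group(1))[0])
        clear_neighborhood(state, mol, mol.diameter())
        assert state.placed == []

    def test_clear_requires_unassigned_atoms(self, scheme):
        mol = normalize_structure("O")
        state = AssignmentState(mol)
        state.place(find_match_candidates(mol, scheme.group(16))[0])
        with pytest.raises(ValueError):
            clear_neighborhood(state, mol, 1)
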