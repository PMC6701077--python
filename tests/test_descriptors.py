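"""Descriptor computation and descriptor-based scheme sorting."""

import random

import pytest

from unifrag import compute_descriptor_vector, parse_scheme, sort_scheme
from unifrag.descriptors import DescriptorVector, count_free_bonds


class TestDescriptorRegeneration:
    def test_all_published_rows_reproduce(self, scheme, published_descriptors):
        """The canonical pattern of every group reproduces its printed row."""
        mismatches = {
            g.group_id: (compute_descriptor_vector(g.patterns[0]),
                         published_descriptors[g.group_id])
            for g in scheme.groups
            if compute_descriptor_vector(g.patterns[0])
            != published_descriptors[g.group_id]
        }
        assert mismatches == {}

    def test_alternate_patterns_agree_on_composition(self, scheme,
                                                     published_descriptors):
        """Every alternate pattern matches its row's atom/hetero/bond counts."""
        for g in scheme.groups:
            ref = published_descriptors[g.group_id]
            for p in g.patterns[1:]:
                v = compute_descriptor_vector(p)
                assert (v.n_atoms, v.n_hetero, v.n_triple, v.n_double) == \
                       (ref.n_atoms, ref.n_hetero, ref.n_triple, ref.n_double), \
                       (g.group_id, p)

    @pytest.mark.parametrize("pattern,expected", [
        # water: a complete molecule, one hetero atom
        ("[OH2]", (True, False, 1, False, 1, False, 0, 0)),
        # vinyl chloride Cl: recursive environment contributes 2 extra atoms
        ("[$(Cl[C]=[C])]", (False, True, 3, True, 1, False, 0, 0)),
        # furfural: whole aromatic molecule with one exocyclic double bond
        ("O=[CH]c1[cH][cH][cH]o1", (True, False, 7, False, 2, True, 0, 1)),
        # negated environments contribute no atoms
        ("[OH0;!$(OC=O);!R][CH2;!R][CH2;!R][OH]", (False, False, 4, True, 2, False, 0, 0)),
        # aromatic CH keeps two open ring connections
        ("[cH]", (False, False, 1, False, 0, True, 0, 0)),
    ])
    def test_spot_values(self, pattern, expected):
        assert tuple(compute_descriptor_vector(pattern)) == expected

    def test_free_bond_counts(self):
        assert count_free_bonds("[OH2]") == 0
        assert count_free_bonds("[CH3;X4]") == 1
        assert count_free_bonds("[CH2]=[CH]") == 1  # double bond eats two valences
        assert count_free_bonds("[cH]") == 2        # open aromatic ring bonds
        assert count_free_bonds("N=C=O") == 1

    def test_zero_and_one_free_bond_mutually_exclusive(self, scheme):
        for p in scheme.all_patterns():
            v = compute_descriptor_vector(p)
            assert not (v.zero_free_bonds and v.one_free_bond)
            assert v.n_atoms >= 1
            assert v.n_hetero <= v.n_atoms


def _toy(rows):
    body = "".join(f"{i},{name},{pat}\n" for i, (name, pat) in enumerate(rows, 1))
    return parse_scheme("group_id,name,patterns\n" + body)


class TestSorting:
    def test_descending_order_on_restricted_scheme(self):
        # methanol (complete) > water (complete, fewer atoms) > CH3
        s = _toy([("CH3", "[CH3;X4]"), ("H2O", "[OH2]"), ("CH3OH", "[CH3][OH]")])
        sort_scheme(s)
        assert [s.groups[i].name for i in s.sorted_order] == ["CH3OH", "H2O", "CH3"]

    def test_singleton_unchanged(self):
        s = _toy([("CH3", "[CH3;X4]")])
        sort_scheme(s)
        assert s.sorted_order == [0]

    def test_ties_keep_file_order(self, scheme):
        # CH2 and CH print identical descriptor rows; file order is kept
        order = list(scheme.iter_in_order(sorted_patterns=True))
        pos = {g.group_id: i for i, g in enumerate(order)}
        assert pos[2] < pos[3]
        assert pos[3] < pos[4]

    def test_sorted_order_is_permutation(self, scheme):
        sort_scheme(scheme)
        assert sorted(scheme.sorted_order) == list(range(len(scheme)))

    def test_sort_idempotent_and_input_order_independent(self, scheme):
        sort_scheme(scheme)
        first = [scheme.groups[i].group_id for i in scheme.sorted_order]
        sort_scheme(scheme)
        assert [scheme.groups[i].group_id for i in scheme.sorted_order] == first

        rng = random.Random(20240901)
        rows = [(g.name, "|".join(g.patterns), g.group_id) for g in scheme.groups]
        rng.shuffle(rows)
        text = "group_id,name,patterns\n" + "".join(
            f"{gid},{name},{pats}\n" for name, pats, gid in rows)
        shuffled = sort_scheme(parse_scheme(text))
        resorted = [shuffled.groups[i].descriptor.sort_key()
                    for i in shuffled.sorted_order]
        original = [scheme.groups[i].descriptor.sort_key()
                    for i in scheme.sorted_order]
        # identical descriptor sequence; ids may differ within tie blocks
        assert resorted == original

    def test_true_sorts_before_false(self):
        a = DescriptorVector(True, False, 1, False, 0, False, 0, 0)
        b = DescriptorVector(False, True, 9, True, 9, True, 9, 9)
        assert a.sort_key() > b.sort_key()
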