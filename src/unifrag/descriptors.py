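"""Heuristic pattern descriptors and descriptor-based scheme sorting.

Each SMARTS pattern of a fragmentation scheme is summarized by eight
descriptors that express how "self-contained" and how specific the pattern
is.  Sorting the scheme in descending lexicographic order of these
descriptors puts complete molecules (water, methanol, ...) first, then
simple halogenated carbons, then larger and more hetero-atom-rich groups
before the generic fallbacks (CH2, ACH, ...).  A greedy fragmenter walking
the scheme in this order finds the conventional UNIFAC assignment for the
vast majority of structures.

The eight descriptors, in sort-priority order:

1.  ``zero_free_bonds`` — the pattern has no open valences (it describes a
    whole molecule).
2.  ``simple`` — the pattern is a single valence-one atom, or one carbon
    carrying only valence-one substituents, with at least one open valence
    (e.g. ``[CH2]Cl``, ``[c]F``, ``C(Cl)(Cl)Cl``).
3.  ``n_atoms`` — atoms defining the group, counting atoms inside positive
    recursive environments but not negated ones.
4.  ``one_free_bond`` — exactly one open valence.
5.  ``n_hetero`` — matched atoms that are neither hydrogen nor carbon.
6.  ``in_ring`` — any matched atom is aromatic or ring-constrained.
7.  ``n_triple`` — triple bonds between matched atoms.
8.  ``n_double`` — double bonds between matched atoms.

Free valences are counted per atom from the declared element, hydrogen
count and the bonds written in the pattern (a double bond consumes two
valences, a triple bond three).  An atom with an ``X<n>`` connectivity
constraint contributes ``n`` minus declared hydrogens minus pattern
neighbors.  An aromatic atom written without explicit ring closures keeps
its unconsumed ring connections as open valences: ``[cH]`` has two open
ring bonds, which is why the aromatic CH group does not count as having a
single free bond.
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

from . import smarts as _sm
from .smarts import AtomSpec, PatternAnalysis

__all__ = [
    "DescriptorVector",
    "compute_descriptor_vector",
    "count_free_bonds",
    "sort_scheme",
]


@dataclass(frozen=True, order=True)
class DescriptorVector:
    """The 8-descriptor summary of one pattern, in sort-priority order."""

    zero_free_bonds: bool
    simple: bool
    n_atoms: int
    one_free_bond: bool
    n_hetero: int
    in_ring: bool
    n_triple: int
    n_double: int

    def sort_key(self) -> tuple[int, ...]:
        """Integer tuple (True=1) compared lexicographically, descending."""
        return tuple(int(v) for v in astuple(self))

    def __iter__(self):
        return iter(astuple(self))


_BOND_ORDER = {"single": 1, "double": 2, "triple": 3, "aromatic": 1}


def _atom_free_bonds(pat: PatternAnalysis, idx: int) -> int:
    """Open valences contributed by one pattern atom."""
    spec = _sm.env_head(pat.atoms[idx])
    incident = pat.incident(idx)
    h = spec.h_count or 0

    if spec.x_count is not None:
        # X counts total connections; every pattern bond consumes one
        return max(0, spec.x_count - h - len(incident))

    if spec.aromatic:
        # two ring connections plus, for carbon, one substituent slot
        ring_bonds = sum(1 for b in incident if b[2] == "aromatic")
        other_bonds = len(incident) - ring_bonds
        subst_slots = 1 if spec.element == "C" else 0
        free_ring = max(0, 2 - ring_bonds)
        free_subst = max(0, subst_slots - h - other_bonds)
        return free_ring + free_subst

    valence = _sm.default_valence(spec.element)
    consumed = sum(_BOND_ORDER[b[2]] for b in incident)
    return max(0, valence - h - consumed)


def count_free_bonds(pattern: str) -> int:
    """Total open valences of a pattern (basis of descriptors 1 and 4)."""
    pat = _sm.analyze_pattern(pattern)
    return sum(_atom_free_bonds(pat, i) for i in range(pat.n_atoms))


def free_bond_profile(pattern: str) -> tuple[int, ...]:
    """Open valences per atom, in pattern atom order."""
    pat = _sm.analyze_pattern(pattern)
    return tuple(_atom_free_bonds(pat, i) for i in range(pat.n_atoms))


def _is_terminal(spec: AtomSpec) -> bool:
    """An atom whose element has default valence one (halogens)."""
    eff = _sm.env_head(spec)
    return eff.element is not None and _sm.default_valence(eff.element) == 1


def _is_simple(pat: PatternAnalysis, free_bonds: int) -> bool:
    if free_bonds == 0:
        return False
    terminals = sum(1 for a in pat.atoms if _is_terminal(a))
    carbons = sum(
        1 for a in pat.atoms
        if not _is_terminal(a) and _sm.env_head(a).element == "C"
    )
    return (
        terminals >= 1
        and carbons <= 1
        and terminals + carbons == pat.n_atoms
    )


def _env_atom_count(env: str) -> int:
    return _sm.compile_query(env).GetNumAtoms()


def compute_descriptor_vector(pattern: str) -> DescriptorVector:
    """Compute the 8 descriptors for one SMARTS pattern."""
    pat = _sm.analyze_pattern(pattern)
    free = sum(_atom_free_bonds(pat, i) for i in range(pat.n_atoms))

    n_atoms = pat.n_atoms
    for spec in pat.atoms:
        for env in spec.positive_envs:
            # the matched atom itself is the head of its environment
            n_atoms += _env_atom_count(env) - 1

    n_hetero = sum(
        1 for a in pat.atoms
        if (_sm.env_head(a).element or "C") not in ("C", "H")
    )
    in_ring = any(a.aromatic or a.ring_positive for a in pat.atoms)
    n_triple = sum(1 for b in pat.bonds if b[2] == "triple")
    n_double = sum(1 for b in pat.bonds if b[2] == "double")

    return DescriptorVector(
        zero_free_bonds=free == 0,
        simple=_is_simple(pat, free),
        n_atoms=n_atoms,
        one_free_bond=free == 1,
        n_hetero=n_hetero,
        in_ring=in_ring,
        n_triple=n_triple,
        n_double=n_double,
    )


def sort_scheme(scheme):
    """Attach descriptors and sort a scheme in descending descriptor order.

    The sort is stable: groups with identical descriptor vectors keep their
    original file order (the published table does not define a tie-break).
    Returns the same scheme object with ``sorted_order`` set.
    """
    scheme.ensure_descriptors()
    order = sorted(
        range(len(scheme.groups)),
        key=lambda i: scheme.groups[i].descriptor.sort_key(),
        reverse=True,
    )
    scheme.sorted_order = order
    return scheme
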