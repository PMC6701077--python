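"""Parent–child containment between the SMARTS patterns of a scheme.

A pattern is a *parent* of another (the *child*) when every occurrence of
the parent embeds an occurrence of the child: CH2 is contained in CONHCH2.
During fragmentation, parents are searched before their children so that a
large group is not eaten piecewise by its fragments.

Containment is decided by substructure-matching the child query against
the parent pattern materialized as a molecular fragment, followed by a
declared-hydrogen compatibility check.  The post-check is needed because a
raw pattern-on-pattern match treats hydrogen counts too loosely: without
it, ``[CH3][OH]`` is reported as contained in ``[CH3][O;H0]`` although a
hydroxyl can never occur at an H0 oxygen.  After a positive match the
declared hydrogen counts are compared atom by atom: a child atom declaring
``Hn`` only maps onto a parent atom that declares the same count; a child
atom with no H declaration maps onto anything.  Connectivity (``X``)
constraints are compared the same way rather than evaluated on the
fragment, because the fragment's open valences would be completed by the
surrounding molecule.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

from . import smarts as _sm

__all__ = ["pattern_contains", "build_parent_child_map"]


@lru_cache(maxsize=4096)
def _pattern_as_fragment(pattern: str) -> Chem.Mol:
    """Materialize a pattern as a concrete molecular fragment.

    Each atom gets its declared element, aromatic flag, formal charge and
    declared hydrogen count (unspecified counts as zero, with implicit
    hydrogens disabled so the count is authoritative).  Recursive-only
    atoms take the element of their environment's head atom.
    """
    pat = _sm.analyze_pattern(pattern)
    rw = Chem.RWMol()
    for spec in pat.atoms:
        eff = _sm.env_head(spec)
        atom = Chem.Atom(eff.element)
        atom.SetIsAromatic(spec.aromatic or eff.aromatic)
        atom.SetFormalCharge(spec.charge)
        atom.SetNumExplicitHs(spec.h_count if spec.h_count is not None
                              else (eff.h_count or 0))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    kinds = {
        "single": Chem.BondType.SINGLE,
        "double": Chem.BondType.DOUBLE,
        "triple": Chem.BondType.TRIPLE,
        "aromatic": Chem.BondType.AROMATIC,
    }
    for i, j, kind in pat.bonds:
        rw.AddBond(i, j, kinds[kind])
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


@lru_cache(maxsize=4096)
def _strip_x_constraints(pattern: str) -> str:
    """Child query with X constraints removed (checked declaratively instead)."""
    out = pattern
    pat = _sm.analyze_pattern(pattern)
    for spec in pat.atoms:
        if spec.x_count is not None:
            for sep in (";", "&"):
                out = out.replace(f"{sep}X{spec.x_count}", "")
            out = out.replace(f"X{spec.x_count}", "")
    return out


def _declared_counts_compatible(parent: str, child: str,
                                mapping: tuple[int, ...]) -> bool:
    from .descriptors import free_bond_profile

    p_pat = _sm.analyze_pattern(parent)
    c_atoms = _sm.analyze_pattern(child).atoms
    p_free = free_bond_profile(parent)
    for child_idx, parent_idx in enumerate(mapping):
        c = c_atoms[child_idx]
        p = _sm.env_head(p_pat.atoms[parent_idx])
        if c.h_count is not None and c.h_count != p.h_count:
            return False
        if c.x_count is not None:
            if p.x_count is not None:
                if c.x_count != p.x_count:
                    return False
            elif p.h_count is not None:
                # realizable connectivity of the parent atom: pattern
                # neighbors + hydrogens + between one bond (if any open
                # valence remains) and one bond per open valence
                base = p_pat.degree(parent_idx) + p.h_count
                free = p_free[parent_idx]
                lo = base + (1 if free > 0 else 0)
                hi = base + free
                if not (lo <= c.x_count <= hi):
                    return False
    return True


def pattern_contains(parent: str, child: str) -> bool:
    """True iff every structure matching ``parent`` embeds ``child``.

    Both arguments are SMARTS strings.  A pattern contains itself.
    """
    parent_frag = _pattern_as_fragment(parent)
    child_query = _sm.compile_query(_strip_x_constraints(child))
    matches = parent_frag.GetSubstructMatches(child_query, uniquify=True)
    return any(
        _declared_counts_compatible(parent, child, m) for m in matches
    )


def build_parent_child_map(scheme) -> dict[str, list[str]]:
    """Map each pattern of the scheme to the patterns that contain it.

    Self-containment and textual duplicates are excluded; the map is
    computed once per scheme and cached on it.  Parents are listed in
    scheme file order.
    """
    patterns = []
    for g in scheme.groups:
        for p in g.patterns:
            if p not in patterns:
                patterns.append(p)
    parent_map: dict[str, list[str]] = {p: [] for p in patterns}
    for child in patterns:
        for parent in patterns:
            if parent == child:
                continue
            if pattern_contains(parent, child):
                parent_map[child].append(parent)
    return parent_map
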