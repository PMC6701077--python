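"""Deterministic test molecules with known fragmentations, plus a
brute-force exact-cover oracle.

The homologous series here have closed-form UNIFAC assignments, so both
fragmenters can be exercised without any external reference data.  The
oracle enumerates *all* exact covers of a molecule's heavy atoms by scheme
matches through naive include/exclude recursion over the candidate list —
deliberately free of the pruning, memoization and ordering heuristics of
the real algorithms, so it can serve as an independent check on them.
"""

from __future__ import annotations

from collections import Counter

from rdkit import Chem

from .engine import Molecule
from .scheme import FragmentationScheme

__all__ = ["FAMILIES", "generate_member", "generate_series", "oracle_enumerate_covers"]

ORACLE_MAX_HEAVY_ATOMS = 10

# group ids used in the closed forms
_CH3, _CH2, _ACH, _ACCH3, _ACCH2, _OH, _CH2CL = 1, 2, 9, 11, 12, 14, 44

FAMILIES = ("n-alkane", "1-alkanol", "chloroalkane", "alkylbenzene")


def generate_member(family: str, n: int) -> tuple[str, Counter]:
    """One member of a homologous series with its expected group counts.

    ``n`` is the number of chain carbons.  Minimum chain lengths: 2 for
    alkanes and alkanols, 2 for chloroalkanes (1-chloro), 1 for
    alkylbenzenes (toluene).
    """
    if family == "n-alkane":
        if n < 2:
            raise ValueError("n-alkane series starts at n=2 (ethane)")
        return "C" * n, Counter({_CH3: 2, _CH2: n - 2})
    if family == "1-alkanol":
        if n < 2:
            raise ValueError("1-alkanol series starts at n=2 (ethanol)")
        return "C" * n + "O", Counter({_CH3: 1, _CH2: n - 1, _OH: 1})
    if family == "chloroalkane":
        if n < 2:
            raise ValueError("chloroalkane series starts at n=2 (chloroethane)")
        return "C" * n + "Cl", Counter({_CH3: 1, _CH2: n - 2, _CH2CL: 1})
    if family == "alkylbenzene":
        if n < 1:
            raise ValueError("alkylbenzene series starts at n=1 (toluene)")
        smiles = "C" * n + "c1ccccc1"
        if n == 1:
            return smiles, Counter({_ACCH3: 1, _ACH: 5})
        return smiles, Counter({_ACCH2: 1, _CH3: 1, _CH2: n - 2, _ACH: 5})
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def generate_series(family: str, n: int, count: int = 1
                    ) -> list[tuple[str, Counter]]:
    """``count`` consecutive members of a series starting at chain length ``n``.

    Zero-count entries are dropped from the expected multisets so they can
    be compared directly against computed group counts.
    """
    out = []
    for k in range(n, n + count):
        smiles, counts = generate_member(family, k)
        out.append((smiles, Counter({g: c for g, c in counts.items() if c > 0})))
    return out


def oracle_enumerate_covers(molecule: Molecule, scheme: FragmentationScheme
                            ) -> set[frozenset[tuple[int, frozenset[int]]]]:
    """All exact covers of the heavy atoms, by naive enumeration.

    Matching goes through fresh RDKit substructure searches rather than
    the engine's candidate machinery, and the recursion considers every
    candidate subset (include/exclude, no pivot atom, no failure cache).
    Exponential by design; refuses molecules above 10 heavy atoms.
    """
    if molecule.n_heavy > ORACLE_MAX_HEAVY_ATOMS:
        raise ValueError("oracle is limited to molecules with <= 10 heavy atoms")
    rdmol = molecule.rdmol
    candidates: list[tuple[int, frozenset[int]]] = []
    seen: set[tuple[int, frozenset[int]]] = set()
    for group in scheme.groups:
        for pattern in group.patterns:
            query = Chem.MolFromSmarts(pattern)
            for match in rdmol.GetSubstructMatches(query, uniquify=True):
                entry = (group.group_id, frozenset(match))
                if entry not in seen:
                    seen.add(entry)
                    candidates.append(entry)

    n = molecule.n_heavy
    covers: set[frozenset[tuple[int, frozenset[int]]]] = set()

    def recurse(idx: int, chosen: list[tuple[int, frozenset[int]]],
                covered: frozenset[int]) -> None:
        if idx == len(candidates):
            if len(covered) == n:
                covers.add(frozenset(chosen))
            return
        recurse(idx + 1, chosen, covered)
        gid, atoms = candidates[idx]
        if not (atoms & covered):
            chosen.append((gid, atoms))
            recurse(idx + 1, chosen, covered | atoms)
            chosen.pop()

    recurse(0, [], frozenset())
    return covers
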