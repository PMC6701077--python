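"""Shared matching machinery for both fragmentation algorithms.

Covers structure normalization (isotope cleanup, salt/radical exclusion),
enumeration of substructure match candidates, the adjacency test used by
the retry phase of the heuristic fragmenter, and the mutable assignment
state that records which heavy atom belongs to which group.

Conventions: heavy atoms are indexed 0-based in RDKit order of the input
SMILES; hydrogens are implicit and never assigned to groups (scheme
patterns address hydrogen only through H-count primitives).  Aromaticity
uses RDKit's default perception model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from rdkit import Chem

from .scheme import Group, FragmentationScheme

__all__ = [
    "Molecule",
    "MatchCandidate",
    "AssignmentState",
    "Fragmentation",
    "FragmentationResult",
    "Status",
    "RejectionError",
    "ParseRejection",
    "ExclusionRejection",
    "MoleculeTooLargeError",
    "normalize_structure",
    "find_match_candidates",
    "is_adjacent",
    "clear_neighborhood",
]


class RejectionError(ValueError):
    """Base class for inputs the fragmenters refuse to process."""


class ParseRejection(RejectionError):
    """The SMILES string could not be parsed."""


class ExclusionRejection(RejectionError):
    """The structure is excluded from fragmentation (salt or radical)."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


class MoleculeTooLargeError(RejectionError):
    """The molecule exceeds the size cap of the exhaustive fragmenter."""


class Status(str, Enum):
    SUCCESS = "success"
    NO_SOLUTION = "no_solution"
    EXCLUDED_INPUT = "excluded_input"


@dataclass
class Molecule:
    """A normalized structure plus cached per-run lookups."""

    rdmol: Chem.Mol
    source_smiles: str
    _match_cache: dict[str, tuple[frozenset[int], ...]] = field(
        default_factory=dict, repr=False)
    _neighbors: list[set[int]] | None = field(default=None, repr=False)
    _dmat: object = field(default=None, repr=False)

    @property
    def n_heavy(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def atom_ids(self) -> frozenset[int]:
        return frozenset(range(self.n_heavy))

    def neighbors(self, idx: int) -> set[int]:
        if self._neighbors is None:
            self._neighbors = [
                {n.GetIdx() for n in a.GetNeighbors()}
                for a in self.rdmol.GetAtoms()
            ]
        return self._neighbors[idx]

    def distance(self, i: int, j: int) -> int:
        if self._dmat is None:
            self._dmat = Chem.GetDistanceMatrix(self.rdmol)
        return int(self._dmat[i][j])

    def diameter(self) -> int:
        """Longest shortest path between heavy atoms (0 for single atoms)."""
        if self.n_heavy <= 1:
            return 0
        if self._dmat is None:
            self._dmat = Chem.GetDistanceMatrix(self.rdmol)
        return int(self._dmat.max())

    def raw_matches(self, pattern: str) -> tuple[frozenset[int], ...]:
        """All symmetry-distinct atom sets matching one pattern (cached)."""
        from . import smarts as _sm
        if pattern not in self._match_cache:
            query = _sm.compile_query(pattern)
            hits = self.rdmol.GetSubstructMatches(query, uniquify=True,
                                                  maxMatches=100000)
            seen: list[frozenset[int]] = []
            for h in hits:
                fs = frozenset(h)
                if fs not in seen:
                    seen.append(fs)
            self._match_cache[pattern] = tuple(seen)
        return self._match_cache[pattern]


@dataclass(frozen=True)
class MatchCandidate:
    """One placeable substructure hit."""

    group_id: int
    pattern_index: int
    atom_ids: frozenset[int]

    def sort_key(self) -> tuple:
        return (self.pattern_index, tuple(sorted(self.atom_ids)))


@dataclass(frozen=True)
class Fragmentation:
    """A set of non-overlapping candidates covering the heavy atoms."""

    candidates: tuple[MatchCandidate, ...]

    @property
    def group_counts(self) -> Counter:
        return Counter(c.group_id for c in self.candidates)

    def atom_partition(self) -> frozenset[tuple[int, frozenset[int]]]:
        """Canonical form for comparing solutions across algorithms."""
        return frozenset((c.group_id, c.atom_ids) for c in self.candidates)


@dataclass
class FragmentationResult:
    """Outcome of one fragmentation run."""

    status: Status
    fragmentation: Fragmentation | None = None
    group_counts: Counter = field(default_factory=Counter)
    iterations_used: int = 0
    solutions: list[Fragmentation] | None = None  # exhaustive algorithm only
    rejection_reason: str | None = None

    @property
    def success(self) -> bool:
        return self.status is Status.SUCCESS


def normalize_structure(smiles: str) -> Molecule:
    """Parse and normalize a SMILES string.

    Heavy hydrogen isotopes (deuterium, tritium) are replaced by ordinary
    hydrogen.  Dot-disconnected inputs (salts, mixtures) and structures
    carrying unpaired electrons are excluded with a typed rejection that is
    distinct from a failure to fragment.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseRejection(f"unparseable SMILES: {smiles!r}")
    if any(a.GetIsotope() for a in mol.GetAtoms()):
        for a in mol.GetAtoms():
            a.SetIsotope(0)
        mol = Chem.RemoveHs(mol)
        Chem.SanitizeMol(mol)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ExclusionRejection("salt", f"multi-fragment structure: {smiles!r}")
    if any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()):
        raise ExclusionRejection("radical", f"radical structure: {smiles!r}")
    return Molecule(rdmol=mol, source_smiles=smiles)


def find_match_candidates(molecule: Molecule, group: Group) -> list[MatchCandidate]:
    """All distinct placements of a group on the molecule.

    Candidates are deduplicated by atom set (automorphic images of a
    pattern on the same atoms count once) and ordered deterministically by
    (pattern index, atom indices); a later pattern never re-reports an
    atom set already produced by an earlier one.
    """
    out: list[MatchCandidate] = []
    seen: set[frozenset[int]] = set()
    for p_idx, pattern in enumerate(group.patterns):
        hits = sorted(molecule.raw_matches(pattern), key=lambda s: tuple(sorted(s)))
        for atoms in hits:
            if atoms in seen:
                continue
            seen.add(atoms)
            out.append(MatchCandidate(group.group_id, p_idx, atoms))
    return out


class AssignmentState:
    """Partial mapping of heavy atoms to placed group candidates."""

    def __init__(self, molecule: Molecule):
        self.molecule = molecule
        self.assigned: dict[int, int] = {}
        self.placed: list[MatchCandidate] = []

    def overlaps(self, candidate: MatchCandidate) -> bool:
        return any(a in self.assigned for a in candidate.atom_ids)

    def place(self, candidate: MatchCandidate) -> None:
        if self.overlaps(candidate):
            raise ValueError("candidate overlaps already-assigned atoms")
        for a in candidate.atom_ids:
            self.assigned[a] = candidate.group_id
        self.placed.append(candidate)

    def remove(self, candidate: MatchCandidate) -> None:
        self.placed.remove(candidate)
        for a in candidate.atom_ids:
            del self.assigned[a]

    @property
    def unassigned(self) -> frozenset[int]:
        return self.molecule.atom_ids - self.assigned.keys()

    @property
    def complete(self) -> bool:
        return len(self.assigned) == self.molecule.n_heavy

    def to_fragmentation(self) -> Fragmentation:
        ordered = sorted(self.placed, key=lambda c: tuple(sorted(c.atom_ids)))
        return Fragmentation(candidates=tuple(ordered))


def is_adjacent(candidate: MatchCandidate, state: AssignmentState,
                molecule: Molecule) -> bool:
    """True iff the state is empty or the candidate touches a placed atom."""
    if not state.assigned:
        return True
    return any(
        n in state.assigned
        for a in candidate.atom_ids
        for n in molecule.neighbors(a)
    )


def clear_neighborhood(state: AssignmentState, molecule: Molecule,
                       iteration: int) -> AssignmentState:
    """Remove placed groups near the unassigned atoms.

    Every placed candidate containing an atom within bond distance
    ``iteration`` of any unassigned atom is removed, freeing the area so
    the adjacency-constrained retry can regrow it differently.  The radius
    grows with the iteration count.
    """
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    unassigned = state.unassigned
    if not unassigned:
        raise ValueError("clear_neighborhood requires at least one unassigned atom")
    doomed = [
        c for c in state.placed
        if any(molecule.distance(a, u) <= iteration
               for a in c.atom_ids for u in unassigned)
    ]
    for c in doomed:
        state.remove(c)
    return state
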