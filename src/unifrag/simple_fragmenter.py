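"""The heuristic (single-solution) fragmentation algorithm.

The algorithm makes one fast sequential pass over the scheme in
descriptor-sorted order, placing every non-overlapping match of each group
as it goes, searching parent patterns before their children so that large
groups are not consumed piecewise.  If atoms remain unassigned, it enters
a retry loop: the area around the unassigned atoms is cleared of placed
groups at a growing bond radius, and the sequential search is repeated
with the extra constraint that new matches must be adjacent to groups
already placed.  The first complete cover found is the solution.
"""

from __future__ import annotations

from .engine import (
    AssignmentState,
    FragmentationResult,
    MatchCandidate,
    Molecule,
    Status,
    clear_neighborhood,
    find_match_candidates,
    is_adjacent,
)
from .scheme import FragmentationScheme, Group

__all__ = ["fragment_simple", "parent_first_search"]


def parent_first_search(molecule: Molecule, group: Group,
                        scheme: FragmentationScheme,
                        state: AssignmentState) -> list[MatchCandidate]:
    """Placeable candidates of a group, with parent-pattern suppression.

    Atoms covered by an *intact* match of a parent pattern (one whose atoms
    are all still unassigned) are withheld from the child: a CH2 lying
    inside an unbroken CONHCH2 site is reserved for the amide group.  Once
    a parent match is blocked by already-placed groups the suppression
    lifts, since the parent can no longer claim the site.
    """
    candidates = [
        c for c in find_match_candidates(molecule, group)
        if not state.overlaps(c)
    ]
    if not candidates:
        return candidates
    suppressed: set[int] = set()
    for pattern in group.patterns:
        for parent in scheme.parents_of(pattern):
            for atoms in molecule.raw_matches(parent):
                if not any(a in state.assigned for a in atoms):
                    suppressed |= atoms
    if not suppressed:
        return candidates
    return [c for c in candidates if not (c.atom_ids & suppressed)]


def _sequential_pass(molecule: Molecule, scheme: FragmentationScheme,
                     state: AssignmentState, sorted_patterns: bool,
                     require_adjacent: bool) -> bool:
    """One ordered scan over the scheme; returns True if anything was placed."""
    progress = False
    for group in scheme.iter_in_order(sorted_patterns):
        for cand in parent_first_search(molecule, group, scheme, state):
            if state.overlaps(cand):
                continue  # an earlier placement in this pass took an atom
            if require_adjacent and not is_adjacent(cand, state, molecule):
                continue
            state.place(cand)
            progress = True
        if state.complete:
            break
    return progress


def fragment_simple(molecule: Molecule, scheme: FragmentationScheme,
                    sorted_patterns: bool = True,
                    max_iterations: int | None = None) -> FragmentationResult:
    """Fragment a normalized molecule with the heuristic algorithm.

    ``sorted_patterns=False`` scans the scheme in file order instead of
    descriptor order (useful to measure how much the sorting contributes).
    The retry cap defaults to the molecule's graph diameter, at which point
    the clearing step has emptied the state and the adjacency-constrained
    search has had one unconstrained restart.
    """
    state = AssignmentState(molecule)
    _sequential_pass(molecule, scheme, state, sorted_patterns,
                     require_adjacent=False)
    if state.complete:
        return _success(state, iterations=0)

    cap = max_iterations if max_iterations is not None else max(1, molecule.diameter())
    for iteration in range(1, cap + 1):
        if state.placed:
            clear_neighborhood(state, molecule, iteration)
        # within one clearing radius, rescan until nothing more fits
        while True:
            progress = _sequential_pass(molecule, scheme, state, sorted_patterns,
                                        require_adjacent=True)
            if state.complete or not progress:
                break
        if state.complete:
            return _success(state, iterations=iteration)
    return FragmentationResult(status=Status.NO_SOLUTION,
                               iterations_used=cap)


def _success(state: AssignmentState, iterations: int) -> FragmentationResult:
    frag = state.to_fragmentation()
    return FragmentationResult(
        status=Status.SUCCESS,
        fragmentation=frag,
        group_counts=frag.group_counts,
        iterations_used=iterations,
    )
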