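"""The exhaustive (all-solutions) fragmentation algorithm.

A recursive tree search enumerates every partition of the heavy atoms into
scheme-group matches.  The branching rule makes it an exact-cover search:
at each node the lowest-index unassigned atom is selected and the search
branches only over candidates covering that atom, so every partition is
generated exactly once.  Residual atom sets proven uncoverable are
memoized and prune repeat encounters.  All solutions are ranked and the
first becomes the chosen fragmentation, preferring fewer, larger groups.
"""

from __future__ import annotations

from .engine import (
    Fragmentation,
    FragmentationResult,
    MatchCandidate,
    Molecule,
    MoleculeTooLargeError,
    Status,
    find_match_candidates,
)
from .scheme import FragmentationScheme

__all__ = ["fragment_complete", "rank_solutions", "DEFAULT_MAX_HEAVY_ATOMS"]

DEFAULT_MAX_HEAVY_ATOMS = 20


def rank_solutions(solutions: list[Fragmentation],
                   scheme: FragmentationScheme) -> list[Fragmentation]:
    """Order solutions so the preferred fragmentation comes first.

    Ascending by total number of placed groups (fewer, larger groups win),
    then by the number of distinct groups used, then by the sorted-scheme
    precedence of the groups (a solution built from higher-priority groups
    ranks earlier).  The sort is stable.
    """
    def key(frag: Fragmentation):
        precedences = tuple(sorted(
            scheme.precedence(c.group_id) for c in frag.candidates
        ))
        return (
            len(frag.candidates),
            len(frag.group_counts),
            precedences,
            tuple(sorted((scheme.precedence(c.group_id), tuple(sorted(c.atom_ids)))
                         for c in frag.candidates)),
        )
    return sorted(solutions, key=key)


def fragment_complete(molecule: Molecule, scheme: FragmentationScheme,
                      sorted_patterns: bool = True,
                      max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS,
                      use_failure_cache: bool = True) -> FragmentationResult:
    """Enumerate all fragmentations of a normalized molecule.

    Molecules above ``max_heavy_atoms`` are rejected (the search is
    exponential in molecule size); callers may fall back to the heuristic
    algorithm.  The ``sorted_patterns`` flag changes only the discovery
    order of solutions, never the solution set; with ranking enabled the
    chosen solution is also order-independent.
    """
    if molecule.n_heavy > max_heavy_atoms:
        raise MoleculeTooLargeError(
            f"{molecule.n_heavy} heavy atoms exceeds cap {max_heavy_atoms}"
        )

    candidates: list[MatchCandidate] = []
    for group in scheme.iter_in_order(sorted_patterns):
        candidates.extend(find_match_candidates(molecule, group))

    atom_to_cands: dict[int, list[MatchCandidate]] = {
        a: [] for a in range(molecule.n_heavy)
    }
    for cand in candidates:
        for a in cand.atom_ids:
            atom_to_cands[a].append(cand)

    all_atoms = molecule.atom_ids
    failed: set[frozenset[int]] = set()
    solutions: list[Fragmentation] = []
    seen_partitions: set[frozenset] = set()

    def search(residual: frozenset[int], placed: list[MatchCandidate]) -> bool:
        if not residual:
            frag = Fragmentation(candidates=tuple(
                sorted(placed, key=lambda c: tuple(sorted(c.atom_ids)))
            ))
            key = frag.atom_partition()
            if key not in seen_partitions:
                seen_partitions.add(key)
                solutions.append(frag)
            return True
        if use_failure_cache and residual in failed:
            return False
        pivot = min(residual)
        any_cover = False
        for cand in atom_to_cands[pivot]:
            if cand.atom_ids <= residual:
                placed.append(cand)
                if search(residual - cand.atom_ids, placed):
                    any_cover = True
                placed.pop()
        if not any_cover and use_failure_cache:
            failed.add(residual)
        return any_cover

    search(all_atoms, [])

    if not solutions:
        return FragmentationResult(status=Status.NO_SOLUTION)
    ranked = rank_solutions(solutions, scheme)
    best = ranked[0]
    return FragmentationResult(
        status=Status.SUCCESS,
        fragmentation=best,
        group_counts=best.group_counts,
        solutions=ranked,
    )


def fragment_combined(molecule: Molecule, scheme: FragmentationScheme,
                      sorted_patterns: bool = True,
                      max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS
                      ) -> FragmentationResult:
    """Heuristic first; exhaustive fallback for structures it cannot cover.

    The fallback only runs for molecules within the exhaustive size cap;
    larger uncovered molecules keep the heuristic's no-solution result.
    """
    from .simple_fragmenter import fragment_simple

    result = fragment_simple(molecule, scheme, sorted_patterns)
    if result.success or molecule.n_heavy > max_heavy_atoms:
        return result
    return fragment_complete(molecule, scheme, sorted_patterns, max_heavy_atoms)
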