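# Methods

## Problem statement

A fragmentation scheme is an ordered list of functional groups, each
defined by one or more SMARTS patterns.  Fragmenting a molecule means
partitioning its heavy atoms into non-overlapping substructure matches of
scheme groups so that every heavy atom is covered exactly once (an exact
cover).  Hydrogens are implicit throughout: every packaged pattern
addresses hydrogen only through H-count primitives, so groups are defined
on heavy atoms and hydrogen placement follows from the matched atoms.

The packaged default scheme encodes the published UNIFAC main-group table
(111 groups, ids 1–109 plus 118/119, with multi-pattern groups where one
group has aromatic or positional variants).  Scheme files are flat CSV
(`group_id,name,patterns`, alternatives `|`-separated) so they are
diff-able and hand-editable; alternative schemes can be dropped in without
code changes.

## Pattern descriptors

Each pattern is reduced to eight descriptors used for prioritization
(listed in sort-priority order, booleans mapped to 1/0):

| # | descriptor | meaning |
|---|------------|---------|
| 1 | zero_free_bonds | no open valences (a complete molecule such as water or methanol) |
| 2 | simple | ≥1 open valence and the pattern is one valence-one atom, or one carbon carrying only valence-one atoms |
| 3 | n_atoms | atoms defining the group, including atoms inside positive recursive environments, excluding negated ones |
| 4 | one_free_bond | exactly one open valence |
| 5 | n_hetero | matched atoms that are neither H nor C |
| 6 | in_ring | any matched atom is aromatic or carries an R constraint |
| 7 | n_triple | triple bonds between matched atoms |
| 8 | n_double | double bonds between matched atoms |

Open valences are computed per atom as (capacity − declared hydrogens −
bonds consumed), clamped at zero, where:

- a declared `X<n>` connectivity is the capacity, and every pattern bond
  consumes one connection;
- otherwise the element's default valence is the capacity and bond *order*
  is consumed (a double bond eats two valences, a triple bond three);
- aromatic atoms have two ring connections plus one substituent slot for
  carbon (none for aromatic N/O/S); ring connections not consumed by
  explicit aromatic bonds in the pattern remain open.  This is why `[cH]`
  has two open valences and the aromatic CH group counts as neither
  zero-bond nor one-bond;
- per-atom clamping at zero absorbs hypervalent sulfur (sulfoxide,
  sulfone) and the charge-separated nitro group without special cases;
- a recursive-only atom such as `[$(Cl[C]=[C])]` takes its element and
  H count from the head atom of its environment; environment bonds do not
  consume valence (the printed one-free-bond value of that row requires
  this reading).

Bonds inside recursive environments never contribute to descriptors 7/8,
and negated environments contribute no atoms to descriptor 3.

A group's descriptor vector is that of its **first (canonical) pattern**.
Alternative patterns of a group are refinements added to widen matching
(e.g. the aromatic variant `[CH2]=[c]` of CH2=C, or the amide variant with
a terminal methyl); they agree with the canonical pattern on the
composition descriptors (3, 5, 7, 8) — which validation enforces — but can
legitimately differ on the bonding/ring descriptors (an aromatic variant
is "in a ring", the methyl-terminated amide variant has one open bond
where the canonical has two).  The full packaged table regenerates the
published per-group descriptor values exactly under these rules
(verified row by row in the test suite).

Sorting is descending lexicographic on the integer-mapped vector and
stable: groups with identical vectors (e.g. CH2/CH/C) keep scheme file
order, since no tie-break is defined for them.  Sorting is therefore
idempotent, and input-order independent up to such ties.

## Parent–child containment

Pattern P is a parent of pattern C when every occurrence of P embeds an
occurrence of C.  The relation is computed once per scheme (O(P²) pairs,
~130 patterns, milliseconds) and cached.  The test materializes the parent
pattern as a concrete molecular fragment — declared hydrogen counts become
explicit H counts with implicit hydrogens disabled, aromatic flags and
bond orders as written — and substructure-matches the child query against
it, with two corrections:

- **Declared hydrogens** are compared atom-by-atom after a match: a child
  atom declaring `Hn` only maps onto a parent atom declaring exactly `Hn`;
  an undeclared child atom maps onto anything.  This removes the classic
  false positive of `[CH3][OH]` being "contained" in `[CH3][O;H0]`.
- **Connectivity (`X`) constraints** are stripped from the child query and
  checked declaratively: against an equal parent `X` declaration, or
  against the parent atom's realizable connectivity range (pattern
  neighbors + declared hydrogens + between one and all of its open
  valences as future neighbors).  Evaluating `X` on the bare fragment
  would be wrong in both directions: a fragment's open valences make
  `[CH3;X4]` unmatchable inside `[c][CH3;X4]`, while naive stripping would
  call `[CH0;X4]` contained in the carbonyl of `[CH3][CH0]=O`, whose
  carbon can only ever reach three connections.

Parents are tracked per pattern, not per group; a group's candidates are
suppressed only on atoms covered by an *intact* parent match (all parent
atoms still unassigned).  Once a parent site is broken by placed groups
the suppression lifts, because the parent can no longer claim it.

## Heuristic fragmentation

Pass 1 scans the scheme in sorted (or, on request, file) order and places
every non-overlapping candidate of each group greedily, in deterministic
candidate order (pattern index, then atom indices).  If the molecule is
fully covered the scan's result is the solution (iterations_used = 0).

Otherwise the retry loop runs with radius r = 1, 2, …: every placed group
within bond distance r of an unassigned atom is removed, then the
sequential scan is repeated — now requiring each new placement to share a
bond with an already-placed group — until a full cover or no further
progress, after which r grows.  The cap is the molecular graph diameter:
at that radius the clearing empties the state entirely, so the search has
had one unconstrained restart before giving up.  Within one radius the
scan iterates to a fixpoint because adjacency may admit a candidate only
after a later group has placed its neighbor.  All steps are deterministic,
so identical inputs give identical results.

## Exhaustive fragmentation

Candidates from all groups are collected once; the search then branches on
the lowest-index uncovered atom, trying every candidate that covers it and
fits in the residual.  This exact-cover branching generates each partition
exactly once; partitions are nevertheless deduplicated by their canonical
(group, atom-set) form as a safety net.  Residual atom sets proven
uncoverable are memoized (coverability of a residual depends only on the
residual), which prunes repeated dead ends; enabling or disabling the
cache provably cannot change the solution set, and a test checks it does
not.  Branch depth is bounded by the heavy-atom count, so the search
terminates.

Solutions are ranked ascending by total number of placed groups (the
published tie-break "fewest patterns", which prefers larger groups), then
by the number of distinct groups, then by the sorted-scheme precedence of
the groups used; the first solution is the chosen fragmentation.  With
this ranking the chosen solution is independent of the scan order, whereas
picking the first-discovered solution would not be.  The default size cap
is 20 heavy atoms, reflecting the exponential growth of the search space;
`fragment_combined` applies the heuristic first and the exhaustive search
as a fallback below the cap.

## Normalization and exclusions

SMILES are parsed and sanitized with RDKit's default aromaticity
perception.  Deuterium/tritium are replaced by ordinary hydrogen (isotope
labels cleared, explicit hydrogens merged).  Dot-disconnected inputs
(salts, mixtures) and structures with unpaired electrons are excluded with
typed rejections distinct from a failure to fragment.  Aromaticity
perception is a known source of disagreement between toolkits and curated
databases; assignments on aromatic/anti-aromatic edge cases follow RDKit's
model.

## Fixtures and the oracle

The test fixtures are generated, never stored: homologous series
(n-alkanes, 1-alkanols, 1-chloroalkanes, n-alkylbenzenes) with closed-form
expected counts — e.g. an n-alkanol with n chain carbons is CH3 + (n−1)·CH2
+ OH — and random alkane trees (max degree 4) whose unique fragmentation
is fixed by each carbon's degree.  An independent brute-force oracle
enumerates all exact covers by include/exclude recursion over raw RDKit
matches, with no pivoting, pruning, memoization or ordering shared with
the real algorithms; it is capped at 10 heavy atoms.  Passing these tests
shows the algorithms are correct on molecules whose chemistry the scheme
covers well; it does not probe the long tail of fused heteroaromatics,
charge-separated species and perception edge cases present in large real
databases, where residual disagreement with curated assignments is
dominated by aromaticity perception rather than by the search itself.

## Known limitations

- The exhaustive search is exponential; above ~20 heavy atoms only the
  heuristic is practical.
- No stereochemistry handling (no packaged pattern is stereo-specific).
- The ranking implements the published "fewest groups" preference only; a
  finer descriptor-based scoring of competing solutions is deliberately
  out of scope.
- Whether an unsorted scan should follow scheme file order is a
  convention; file order is used, so unsorted-run statistics are
  qualitative.
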