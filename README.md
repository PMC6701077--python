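# unifrag

Automatic fragmentation of molecules into UNIFAC functional groups.

Group-contribution methods predict thermophysical properties by summing the
contributions of a molecule's functional groups, so applying one to a large
set of structures first requires mapping every molecule onto a
non-overlapping set of groups that covers all of its heavy atoms — an exact
cover of the molecular graph by substructure matches.  Doing this by hand
does not scale, and doing it naively by machine runs into two classic
failure modes: *non-unique assignment* (an ACOH site can also be read as
AC + OH) and *incomplete assignment* (if the aromatic CH/C patterns consume
a ring before the chlorine pattern runs, the Cl atom is stranded).

`unifrag` implements two fragmentation algorithms over SMARTS-based
fragmentation schemes, with the published UNIFAC group table packaged as the
default scheme:

- **Heuristic fragmenter** (`fragment_simple`): each pattern is summarized
  by eight descriptors — d1: no open valences; d2: a "simple" halogenated
  carbon or lone valence-one atom; d3: number of atoms defining the group
  (including positive recursive-environment atoms); d4: exactly one open
  valence; d5: non-C/H atom count; d6: ring/aromatic membership; d7/d8:
  triple/double bond counts.  The scheme is sorted in descending
  lexicographic order of (d1, …, d8) and scanned greedily, searching parent
  patterns (patterns that contain a group's pattern) before the group
  itself so that e.g. a CH2 inside an intact CONHCH2 site is reserved for
  the amide.  If atoms remain unassigned, the area around them is cleared
  at a growing bond radius and the scan is repeated with new matches
  constrained to be adjacent to groups already placed.
- **Exhaustive fragmenter** (`fragment_complete`): a recursive exact-cover
  tree search that enumerates *every* partition of the heavy atoms into
  group matches, memoizes uncoverable residual atom sets, and ranks
  solutions (fewest groups first, i.e. larger groups win).  Intended for
  molecules up to ~20 heavy atoms; `fragment_combined` runs the heuristic
  first and falls back to the exhaustive search.

Structures are normalized before fragmentation: heavy hydrogen isotopes are
replaced by ordinary hydrogen, and salts (dot-disconnected SMILES) and
radicals are excluded with a typed rejection.

## Worked example

```python
>>> from unifrag import load_default_scheme, normalize_structure, fragment_simple
>>> scheme = load_default_scheme()
>>> mol = normalize_structure("c1c(Cl)c([OH])ccc1")   # 2-chlorophenol
>>> result = fragment_simple(mol, scheme)
>>> result.status.value
'success'
>>> {scheme.group(g).name: c for g, c in result.group_counts.items()}
{'ACH': 4, 'ACCl': 1, 'ACOH': 1}
```

The molecule is covered by four aromatic CH groups, one aromatic-chlorine
group and one aromatic-hydroxyl group — the conventional UNIFAC
assignment.  Scanning the scheme unsorted instead strands the chlorine
behind the generic aromatic patterns and only the retry phase rescues the
run, landing on the reference-unlike AC + OH split; the descriptor sorting
is what makes the first answer the right one.

The same is available from the shell:

```bash
unifrag fragment --algorithm simple --input molecules.smi --output out.csv
unifrag scheme-sort src/unifrag/data/unifac_table1.csv sorted_scheme.csv
unifrag make-fixtures --out ref.csv && unifrag compare --reference ref.csv
```

`fragment` writes one row per input SMILES with its status (`success`,
`no_solution`, or `excluded_input`), the group counts as `id:count` pairs,
and the number of retry iterations used.  `compare` scores a run against a
reference database of expected group counts and reports how many
structures were fragmented and how many match the reference exactly.

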