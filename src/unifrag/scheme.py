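"""Fragmentation schemes: parsing, validation, and the packaged UNIFAC table.

A fragmentation scheme is an ordered list of functional groups.  Each group
has a numeric identifier (here: the published UNIFAC main-list numbers,
1–119 with gaps), a short name, and one or more SMARTS patterns that locate
the group in a molecule.  The scheme file format is a flat CSV with columns
``group_id,name,patterns`` where alternative patterns are ``|``-separated
(the published table separates them with commas, which would collide with
CSV).

The packaged default scheme ``unifac_table1.csv`` encodes the full UNIFAC
group table, including the multi-pattern groups and the refined patterns
(recursive environments, ``!R`` qualifiers) exactly as published.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

from . import descriptors as _desc
from . import smarts as _sm

__all__ = [
    "Group",
    "FragmentationScheme",
    "SchemeError",
    "parse_scheme",
    "serialize_scheme",
    "validate_scheme",
    "load_scheme",
    "load_default_scheme",
]

PATTERN_SEPARATOR = "|"
DEFAULT_SCHEME_RESOURCE = "unifac_table1.csv"


class SchemeError(ValueError):
    """Raised for scheme files that cannot be parsed."""


@dataclass
class Group:
    """One scheme entry: an identifier, a name, and its SMARTS patterns.

    The first pattern is the canonical one; later patterns are refinements
    added to widen matching (e.g. the aromatic variants of CH2=C).  The
    group's descriptor vector is computed from the canonical pattern.
    """

    group_id: int
    name: str
    patterns: tuple[str, ...]
    descriptor: _desc.DescriptorVector | None = None

    def __post_init__(self):
        if not self.patterns:
            raise SchemeError(f"group {self.group_id} has no patterns")

    @property
    def queries(self) -> tuple[Chem.Mol, ...]:
        return tuple(_sm.compile_query(p) for p in self.patterns)


@dataclass
class FragmentationScheme:
    """Ordered collection of groups plus derived lookup structures."""

    groups: list[Group]
    sorted_order: list[int] | None = None
    # pattern string -> list of pattern strings that contain it
    parent_child: dict[str, list[str]] | None = None
    _by_id: dict[int, Group] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {g.group_id: g for g in self.groups}

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def group(self, group_id: int) -> Group:
        return self._by_id[group_id]

    def group_by_name(self, name: str) -> Group:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def iter_in_order(self, sorted_patterns: bool = True):
        """Yield groups in descriptor-sorted order (or file order)."""
        if sorted_patterns:
            if self.sorted_order is None:
                _desc.sort_scheme(self)
            for i in self.sorted_order:
                yield self.groups[i]
        else:
            yield from self.groups

    def ensure_descriptors(self) -> None:
        for g in self.groups:
            if g.descriptor is None:
                g.descriptor = _desc.compute_descriptor_vector(g.patterns[0])

    def precedence(self, group_id: int) -> int:
        """Rank of a group in the sorted scheme (0 = highest priority)."""
        if self.sorted_order is None:
            _desc.sort_scheme(self)
        for rank, idx in enumerate(self.sorted_order):
            if self.groups[idx].group_id == group_id:
                return rank
        raise KeyError(group_id)

    def ensure_relations(self) -> None:
        if self.parent_child is None:
            from .relations import build_parent_child_map
            self.parent_child = build_parent_child_map(self)

    def parents_of(self, pattern: str) -> list[str]:
        self.ensure_relations()
        return self.parent_child.get(pattern, [])

    def all_patterns(self) -> list[str]:
        return [p for g in self.groups for p in g.patterns]


def parse_scheme(source: str) -> FragmentationScheme:
    """Parse scheme-file content (CSV text) into a FragmentationScheme.

    SMARTS are compiled eagerly so malformed patterns fail here, with the
    offending group named.  File order is preserved.
    """
    reader = csv.DictReader(io.StringIO(source))
    groups: list[Group] = []
    seen: set[int] = set()
    if reader.fieldnames is not None:
        missing = {"group_id", "name", "patterns"} - set(reader.fieldnames)
        if missing:
            raise SchemeError(f"scheme file is missing columns: {sorted(missing)}")
    for row in reader:
        try:
            gid = int(row["group_id"])
        except (TypeError, ValueError):
            raise SchemeError(f"bad group_id {row.get('group_id')!r}") from None
        if gid in seen:
            raise SchemeError(f"duplicate group_id {gid}")
        seen.add(gid)
        patterns = tuple(p.strip() for p in row["patterns"].split(PATTERN_SEPARATOR))
        for p in patterns:
            if Chem.MolFromSmarts(p) is None:
                raise SchemeError(f"group {gid}: invalid SMARTS {p!r}")
        groups.append(Group(group_id=gid, name=row["name"].strip(), patterns=patterns))
    return FragmentationScheme(groups=groups)


def serialize_scheme(scheme: FragmentationScheme, with_descriptors: bool = False,
                     sorted_patterns: bool = False) -> str:
    """Write a scheme back to CSV text (round-trips with parse_scheme)."""
    buf = io.StringIO()
    fields = ["group_id", "name", "patterns"]
    if with_descriptors:
        scheme.ensure_descriptors()
        fields += [
            "zero_free_bonds", "simple", "n_atoms", "one_free_bond",
            "n_hetero", "in_ring", "n_triple", "n_double",
        ]
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(fields)
    for g in scheme.iter_in_order(sorted_patterns) if sorted_patterns else scheme.groups:
        row = [g.group_id, g.name, PATTERN_SEPARATOR.join(g.patterns)]
        if with_descriptors:
            row += list(g.descriptor)
        writer.writerow(row)
    return buf.getvalue()


def validate_scheme(scheme: FragmentationScheme) -> list[str]:
    """Return human-readable diagnostics (empty for a healthy scheme).

    Checks every pattern parses and analyzes, that group ids are unique
    (re-checked for schemes built programmatically), and that alternative
    patterns of one group agree with the canonical pattern on the
    composition descriptors (atom count, hetero count, triple/double
    bonds).  The bonding descriptors may legitimately differ between a
    canonical pattern and a refined variant (an aromatic variant of an
    aliphatic pattern has different open valences), so they are not
    required to agree.
    """
    diagnostics: list[str] = []
    seen: set[int] = set()
    for g in scheme.groups:
        if g.group_id in seen:
            diagnostics.append(f"duplicate group_id {g.group_id}")
        seen.add(g.group_id)
        vectors = []
        for p in g.patterns:
            if Chem.MolFromSmarts(p) is None:
                diagnostics.append(f"group {g.group_id} ({g.name}): invalid SMARTS {p!r}")
                continue
            try:
                vectors.append((p, _desc.compute_descriptor_vector(p)))
            except _sm.SmartsError as exc:
                diagnostics.append(f"group {g.group_id} ({g.name}): {exc}")
        if len(vectors) > 1:
            ref_p, ref_v = vectors[0]
            for p, v in vectors[1:]:
                disagreements = [
                    name for name in ("n_atoms", "n_hetero", "n_triple", "n_double")
                    if getattr(v, name) != getattr(ref_v, name)
                ]
                if disagreements:
                    diagnostics.append(
                        f"group {g.group_id} ({g.name}): pattern {p!r} disagrees "
                        f"with {ref_p!r} on {', '.join(disagreements)}"
                    )
    return diagnostics


def load_scheme(path: str | Path) -> FragmentationScheme:
    """Load a scheme from a CSV file on disk."""
    return parse_scheme(Path(path).read_text(encoding="utf-8"))


def load_default_scheme() -> FragmentationScheme:
    """Load the packaged UNIFAC scheme."""
    text = resources.files("unifrag.data").joinpath(DEFAULT_SCHEME_RESOURCE).read_text("utf-8")
    return parse_scheme(text)
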