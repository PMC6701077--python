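"""Comparison of computed fragmentations against a reference database.

A reference file maps SMILES strings to expected group-count multisets
(CSV columns ``smiles,expected_counts`` with counts written as ``id:count``
pairs joined by ``;``).  A comparison run fragments every entry and
reports how many structures could be fragmented at all and how many
reproduce the reference assignment exactly.  Percentages use the total
number of input SMILES as denominator.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .engine import FragmentationResult, RejectionError, Status, normalize_structure
from .scheme import FragmentationScheme

__all__ = [
    "ReferenceEntry",
    "RunSummary",
    "compare_counts",
    "load_reference",
    "parse_counts",
    "format_counts",
    "run_comparison",
    "summarize_run",
]


@dataclass(frozen=True)
class ReferenceEntry:
    smiles: str
    expected_counts: Counter


@dataclass
class Verdict:
    smiles: str
    status: str
    match: bool


@dataclass
class RunSummary:
    n_input: int = 0
    n_excluded: int = 0
    n_fragmented: int = 0
    n_like_reference: int = 0
    verdicts: list[Verdict] = field(default_factory=list)

    @property
    def pct_fragmented(self) -> float:
        return 100.0 * self.n_fragmented / self.n_input if self.n_input else 0.0

    @property
    def pct_like_reference(self) -> float:
        return 100.0 * self.n_like_reference / self.n_input if self.n_input else 0.0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_fragmented": self.n_fragmented,
            "n_like_reference": self.n_like_reference,
            "pct_fragmented": round(self.pct_fragmented, 2),
            "pct_like_reference": round(self.pct_like_reference, 2),
        }


def parse_counts(text: str) -> Counter:
    """Parse ``'1:2;2:3'`` into a group-count multiset."""
    counts: Counter = Counter()
    text = text.strip()
    if not text:
        return counts
    for pair in text.split(";"):
        gid, _, cnt = pair.partition(":")
        counts[int(gid)] += int(cnt)
    return counts


def format_counts(counts: Counter) -> str:
    return ";".join(f"{g}:{c}" for g, c in sorted(counts.items()))


def compare_counts(computed: Counter, expected: Counter) -> bool:
    """True iff the multisets are identical (ids and counts)."""
    return {g: c for g, c in computed.items() if c} == \
           {g: c for g, c in expected.items() if c}


def load_reference(source: str | Path) -> list[ReferenceEntry]:
    """Load a reference CSV from a path or from CSV text."""
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) \
        else source
    reader = csv.DictReader(io.StringIO(text))
    return [
        ReferenceEntry(row["smiles"].strip(), parse_counts(row["expected_counts"]))
        for row in reader
    ]


def summarize_run(entries: list[ReferenceEntry],
                  results: list[FragmentationResult]) -> RunSummary:
    """Aggregate per-molecule outcomes into a run summary."""
    if len(entries) != len(results):
        raise ValueError("entries and results must be aligned")
    summary = RunSummary(n_input=len(entries))
    for entry, result in zip(entries, results):
        if result.status is Status.EXCLUDED_INPUT:
            summary.n_excluded += 1
            summary.verdicts.append(Verdict(entry.smiles, result.status.value, False))
            continue
        match = False
        if result.success:
            summary.n_fragmented += 1
            match = compare_counts(result.group_counts, entry.expected_counts)
            if match:
                summary.n_like_reference += 1
        summary.verdicts.append(Verdict(entry.smiles, result.status.value, match))
    return summary


def run_comparison(entries: list[ReferenceEntry], scheme: FragmentationScheme,
                   algorithm: str = "simple", sorted_patterns: bool = True,
                   max_heavy_atoms: int = 20) -> RunSummary:
    """Fragment every reference entry and summarize agreement."""
    from .complete_fragmenter import fragment_combined, fragment_complete
    from .engine import MoleculeTooLargeError
    from .simple_fragmenter import fragment_simple

    results: list[FragmentationResult] = []
    for entry in entries:
        try:
            molecule = normalize_structure(entry.smiles)
        except RejectionError as exc:
            results.append(FragmentationResult(
                status=Status.EXCLUDED_INPUT,
                rejection_reason=getattr(exc, "reason", "parse"),
            ))
            continue
        try:
            if algorithm == "simple":
                res = fragment_simple(molecule, scheme, sorted_patterns)
            elif algorithm == "complete":
                res = fragment_complete(molecule, scheme, sorted_patterns,
                                        max_heavy_atoms)
            elif algorithm == "combined":
                res = fragment_combined(molecule, scheme, sorted_patterns,
                                        max_heavy_atoms)
            else:
                raise ValueError(f"unknown algorithm {algorithm!r}")
        except MoleculeTooLargeError:
            res = FragmentationResult(status=Status.EXCLUDED_INPUT,
                                      rejection_reason="too_large")
        results.append(res)
    return summarize_run(entries, results)
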