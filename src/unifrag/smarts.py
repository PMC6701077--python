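"""Structural analysis of the SMARTS primitives used in fragmentation schemes.

RDKit parses a SMARTS pattern into a query molecule, which gives us the
atom/bond graph (including ring closures).  What it does not expose in a
declarative form are the *primitives* written on each atom — the declared
hydrogen count ``H2``, the connectivity constraint ``X4``, ring constraints
``R``/``!R`` and recursive environments ``$(...)`` — which the descriptor
computation and the parent/child containment test both need.  This module
tokenizes the original pattern text into per-atom primitive strings (aligned
with RDKit's atom order, which follows order of appearance) and interprets
the small primitive vocabulary that group-contribution schemes use.

Supported atom primitives: element symbols (aromatic and aliphatic),
``H<n>``, ``X<n>``, formal charges, ``R``/``!R``, and positive/negated
recursive environments.  This covers the full published UNIFAC scheme;
anything outside it fails loudly rather than being silently misread.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

__all__ = [
    "AtomSpec",
    "PatternAnalysis",
    "SmartsError",
    "analyze_pattern",
    "compile_query",
    "tokenize_atoms",
]

# default valences used for free-bond accounting (neutral organic subset)
_VALENCE = {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
    "Si": 4, "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1,
}

_TWO_LETTER = ("Cl", "Br", "Si")
_ONE_LETTER = "BCNOPSFIbcnosp"

_ELEMENT_RE = re.compile(r"(Si|Cl|Br|I|F|B|C|N|O|P|S|c|n|o|p|s)")
_HCOUNT_RE = re.compile(r"H(\d*)")
_XCOUNT_RE = re.compile(r"X(\d+)")
_CHARGE_RE = re.compile(r"(\+{1,2}|-{1,2})(\d*)")


class SmartsError(ValueError):
    """Raised for SMARTS that cannot be parsed or analyzed."""


@dataclass(frozen=True)
class AtomSpec:
    """Interpreted primitives of a single SMARTS atom expression."""

    raw: str
    element: str | None
    aromatic: bool
    h_count: int | None          # declared H count, None if unspecified
    x_count: int | None          # declared total connectivity, None if unspecified
    charge: int
    ring_positive: bool          # carries an unnegated R constraint
    ring_negative: bool
    positive_envs: tuple[str, ...] = ()
    negated_envs: tuple[str, ...] = ()

    @property
    def recursive_only(self) -> bool:
        """True when the atom is defined solely by a recursive environment."""
        return self.element is None and bool(self.positive_envs)


@dataclass(frozen=True)
class PatternAnalysis:
    """A SMARTS pattern together with its interpreted atom primitives."""

    smarts: str
    atoms: tuple[AtomSpec, ...]
    # bonds as (begin, end, kind) with kind in {"single", "double", "triple", "aromatic"}
    bonds: tuple[tuple[int, int, str], ...] = field(default=())

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degree(self, idx: int) -> int:
        return sum(1 for i, j, _ in self.bonds if idx in (i, j))

    def incident(self, idx: int) -> list[tuple[int, int, str]]:
        return [b for b in self.bonds if idx in b[:2]]


def _split_envs(body: str) -> tuple[str, list[str], list[str]]:
    """Remove recursive environments from a bracket-atom body.

    Returns the remaining primitive text plus the positive and negated
    environment SMARTS (without the ``$(`` ``)`` wrapper).
    """
    out: list[str] = []
    pos: list[str] = []
    neg: list[str] = []
    i = 0
    while i < len(body):
        negated = body.startswith("!$(", i)
        if negated or body.startswith("$(", i):
            j = body.index("(", i)
            depth = 0
            k = j
            while k < len(body):
                if body[k] == "(":
                    depth += 1
                elif body[k] == ")":
                    depth -= 1
                    if depth == 0:
                        break
                k += 1
            if depth != 0:
                raise SmartsError(f"unbalanced recursive environment in {body!r}")
            (neg if negated else pos).append(body[j + 1:k])
            i = k + 1
        else:
            out.append(body[i])
            i += 1
    return "".join(out), pos, neg


def tokenize_atoms(smarts: str) -> list[str]:
    """Split a SMARTS string into atom primitive texts in atom order.

    Bracket atoms keep their brackets; bare atoms are returned as written.
    The order matches RDKit's atom indexing for the same pattern.
    """
    tokens: list[str] = []
    i = 0
    n = len(smarts)
    while i < n:
        c = smarts[i]
        if c == "[":
            depth = 0
            j = i
            while j < n:
                if smarts[j] == "[":
                    depth += 1
                elif smarts[j] == "]":
                    depth -= 1
                    if depth == 0:
                        break
                j += 1
            if depth != 0:
                raise SmartsError(f"unbalanced brackets in {smarts!r}")
            tokens.append(smarts[i:j + 1])
            i = j + 1
        elif smarts[i:i + 2] in _TWO_LETTER:
            tokens.append(smarts[i:i + 2])
            i += 2
        elif c in _ONE_LETTER:
            tokens.append(c)
            i += 1
        elif c in "()=#-~:@/\\.%" or c.isdigit():
            i += 1
        else:
            raise SmartsError(f"unsupported SMARTS token {c!r} in {smarts!r}")
    return tokens


def parse_atom_token(token: str) -> AtomSpec:
    """Interpret one atom primitive string."""
    if not token.startswith("["):
        return _parse_bare(token)
    body = token[1:-1]
    body, pos_envs, neg_envs = _split_envs(body)

    m = _ELEMENT_RE.search(body)
    element = None
    aromatic = False
    rest = body
    if m:
        sym = m.group(1)
        aromatic = sym.islower()
        element = sym.upper() if len(sym) == 1 else sym
        rest = body[:m.start()] + body[m.end():]

    h_count = None
    hm = _HCOUNT_RE.search(rest)
    if hm:
        h_count = int(hm.group(1)) if hm.group(1) else 1
        rest = rest[:hm.start()] + rest[hm.end():]

    x_count = None
    xm = _XCOUNT_RE.search(rest)
    if xm:
        x_count = int(xm.group(1))
        rest = rest[:xm.start()] + rest[xm.end():]

    charge = 0
    cm = _CHARGE_RE.search(rest)
    if cm:
        sign = 1 if cm.group(1)[0] == "+" else -1
        mag = int(cm.group(2)) if cm.group(2) else len(cm.group(1))
        charge = sign * mag
        rest = rest[:cm.start()] + rest[cm.end():]

    ring_negative = "!R" in rest
    ring_positive = bool(re.search(r"(?<!!)R", rest))

    leftovers = rest.replace("!R", "").replace("R", "").replace(";", "").replace("&", "")
    if leftovers.strip():
        raise SmartsError(f"unsupported primitives {leftovers!r} in atom {token!r}")

    if element is None and not pos_envs:
        raise SmartsError(f"atom {token!r} has neither an element nor a positive environment")

    return AtomSpec(
        raw=token, element=element, aromatic=aromatic,
        h_count=h_count, x_count=x_count, charge=charge,
        ring_positive=ring_positive, ring_negative=ring_negative,
        positive_envs=tuple(pos_envs), negated_envs=tuple(neg_envs),
    )


def _parse_bare(token: str) -> AtomSpec:
    aromatic = token[0].islower()
    element = token if len(token) > 1 else token.upper()
    return AtomSpec(
        raw=token, element=element, aromatic=aromatic,
        h_count=None, x_count=None, charge=0,
        ring_positive=False, ring_negative=False,
    )


_BOND_KIND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
    Chem.BondType.UNSPECIFIED: "single",
}


@lru_cache(maxsize=4096)
def compile_query(smarts: str) -> Chem.Mol:
    """Compile a SMARTS pattern to an RDKit query molecule (cached)."""
    mol = Chem.MolFromSmarts(smarts)
    if mol is None:
        raise SmartsError(f"invalid SMARTS: {smarts!r}")
    return mol


@lru_cache(maxsize=4096)
def analyze_pattern(smarts: str) -> PatternAnalysis:
    """Tokenize and interpret a pattern, cross-checked against RDKit's graph."""
    mol = compile_query(smarts)
    tokens = tokenize_atoms(smarts)
    if len(tokens) != mol.GetNumAtoms():
        raise SmartsError(
            f"primitive tokenizer found {len(tokens)} atoms but RDKit found "
            f"{mol.GetNumAtoms()} in {smarts!r}"
        )
    atoms = tuple(parse_atom_token(t) for t in tokens)
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_KIND[b.GetBondType()])
        for b in mol.GetBonds()
    )
    return PatternAnalysis(smarts=smarts, atoms=atoms, bonds=bonds)


def env_head(spec: AtomSpec) -> AtomSpec:
    """The first atom of a recursive-only atom's environment.

    For a pattern like ``[$(Cl[C]=[C])]`` the matched atom *is* the first
    environment atom (the chlorine); its element and hydrogen count are
    taken from there.
    """
    if not spec.recursive_only:
        return spec
    head_token = tokenize_atoms(spec.positive_envs[0])[0]
    return parse_atom_token(head_token)


def default_valence(element: str) -> int:
    try:
        return _VALENCE[element]
    except KeyError:
        raise SmartsError(f"no default valence for element {element!r}") from None
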