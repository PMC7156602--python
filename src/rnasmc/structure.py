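"""RNA secondary structures and their loop decomposition.

A pseudoknot-free secondary structure is a nested set of base pairs over a
sequence, written in dot-bracket notation ('(' / ')' paired, '.' unpaired).
The decomposition splits a structure into the five element kinds used by the
RNAsmc similarity score:

* stem (S) — a maximal run of consecutively stacked pairs,
* hairpin loop (H) — unpaired bases closed by a single pair,
* bulge loop (B) — unpaired bases on exactly one side between two helices,
* interior loop (I) — unpaired bases on both sides between two helices,
* multibranch loop (M) — a loop from which three or more helices emanate.

Unpaired bases outside every pair (the exterior loop) belong to no element.
All coordinates are 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "ElementKind",
    "StructuralElement",
    "ElementDecomposition",
    "StructureFormatError",
    "parse_dotbracket",
    "decompose",
]

_VALID_BASES = frozenset("ACGU")


class StructureFormatError(ValueError):
    """Raised for malformed dot-bracket / CT input or invalid pairings."""


def normalize_bases(bases: str) -> str:
    """Uppercase and convert DNA-convention T to U."""
    return bases.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}; T is accepted and normalized to U."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize_bases(self.bases))
        if len(self.bases) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, pos: int) -> str:
        """1-based base access."""
        if not 1 <= pos <= len(self.bases):
            raise IndexError(f"position {pos} outside [1, {len(self.bases)}]")
        return self.bases[pos - 1]


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence plus a nested pairing.

    ``pair_table`` maps 1-based position i to its partner j (and j to i);
    unpaired positions are absent.
    """

    sequence: RnaSequence
    dotbracket: str
    pair_table: Mapping[int, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def partner(self, pos: int) -> int:
        """Pairing partner of 1-based ``pos``, or 0 if unpaired."""
        return self.pair_table.get(pos, 0)

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, sorted by i."""
        return sorted((i, j) for i, j in self.pair_table.items() if i < j)


class ElementKind(str, enum.Enum):
    """The five structural element kinds of the RNAsmc decomposition."""

    S = "S"  # stem
    H = "H"  # hairpin loop
    I = "I"  # interior loop
    B = "B"  # bulge loop
    M = "M"  # multibranch loop

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StructuralElement:
    """One element: its kind, member positions, and bounding pairs.

    For stems, ``positions`` holds the paired bases of both strands.  For
    loops, ``positions`` holds the unpaired loop bases; it is empty for
    degenerate junctions with no unpaired base (e.g. a multiloop whose
    helices abut directly).
    """

    kind: ElementKind
    positions: frozenset[int]
    closing_pairs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class ElementDecomposition:
    """Per-kind position sets (u_p) and element counts (u_n) of a structure."""

    elements: tuple[StructuralElement, ...]
    u_p: Mapping[ElementKind, frozenset[int]]
    u_n: Mapping[ElementKind, int]

    @classmethod
    def from_elements(
        cls, elements: Iterable[StructuralElement]
    ) -> "ElementDecomposition":
        elements = tuple(elements)
        u_p: dict[ElementKind, frozenset[int]] = {}
        u_n: dict[ElementKind, int] = {}
        for kind in ElementKind:
            of_kind = [e for e in elements if e.kind is kind]
            u_n[kind] = len(of_kind)
            pos: set[int] = set()
            for e in of_kind:
                pos |= e.positions
            u_p[kind] = frozenset(pos)
        return cls(elements=elements, u_p=u_p, u_n=u_n)


def parse_dotbracket(db: str, seq: str, seq_id: str = "seq") -> SecondaryStructure:
    """Parse a dot-bracket string over a sequence into a validated structure.

    Raises :class:`StructureFormatError` on length mismatch, stray
    characters, or unbalanced brackets.
    """
    sequence = RnaSequence(seq_id, seq)
    if len(db) != len(sequence):
        raise StructureFormatError(
            f"structure length {len(db)} != sequence length {len(sequence)}"
        )
    bad = set(db) - set("().")
    if bad:
        raise StructureFormatError(f"invalid dot-bracket characters: {sorted(bad)}")
    pair_table: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureFormatError(f"unmatched ')' at position {pos}")
            i = stack.pop()
            pair_table[i] = pos
            pair_table[pos] = i
    if stack:
        raise StructureFormatError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(sequence=sequence, dotbracket=db, pair_table=pair_table)


def structure_from_pairs(
    sequence: RnaSequence, pairs: Iterable[tuple[int, int]]
) -> SecondaryStructure:
    """Build a structure from explicit (i, j) pairs, validating nesting.

    Pseudoknots (crossing pairs) are rejected, as are conflicting or
    out-of-range pairs.
    """
    n = len(sequence)
    pair_table: dict[int, int] = {}
    norm: list[tuple[int, int]] = []
    for i, j in pairs:
        if i == j:
            raise StructureFormatError(f"base {i} paired with itself")
        i, j = (i, j) if i < j else (j, i)
        if not (1 <= i <= n and 1 <= j <= n):
            raise StructureFormatError(f"pair ({i},{j}) outside [1,{n}]")
        for p in (i, j):
            if p in pair_table and pair_table[p] != (j if p == i else i):
                raise StructureFormatError(f"position {p} paired twice")
        pair_table[i] = j
        pair_table[j] = i
        norm.append((i, j))
    norm = sorted(set(norm))
    for a in range(len(norm)):
        i, j = norm[a]
        for b in range(a + 1, len(norm)):
            k, l = norm[b]
            if i < k < j < l:
                raise StructureFormatError(
                    f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross"
                )
    db = "".join(
        "(" if pair_table.get(p, 0) > p else ")" if pair_table.get(p, 0) else "."
        for p in range(1, n + 1)
    )
    return SecondaryStructure(sequence=sequence, dotbracket=db, pair_table=pair_table)


def _direct_children(
    struct: SecondaryStructure, i: int, j: int
) -> tuple[list[tuple[int, int]], list[int]]:
    """Pairs directly enclosed by (i, j) and the loop's unpaired positions."""
    children: list[tuple[int, int]] = []
    unpaired: list[int] = []
    k = i + 1
    while k < j:
        partner = struct.partner(k)
        if partner:
            children.append((k, partner))
            k = partner + 1
        else:
            unpaired.append(k)
            k += 1
    return children, unpaired


def decompose(struct: SecondaryStructure) -> ElementDecomposition:
    """Decompose a nested structure into stems and the four loop kinds.

    For each closing pair the directly enclosed branches determine the loop
    kind (0 branches: hairpin; 1 stacked branch: part of a stem; 1 offset
    branch: bulge or interior loop; >=2 branches: multibranch loop).  Stems
    are maximal stacked runs; their positions cover both paired strands.
    Exterior unpaired bases belong to no element.
    """
    elements: list[StructuralElement] = []

    # Stems: start at a pair whose outer neighbour is not a pair of the
    # same helix, extend inward while consecutively stacked.
    opening = sorted(i for i, j in struct.pair_table.items() if i < j)
    in_stem: set[int] = set()
    for i in opening:
        if i in in_stem:
            continue
        j = struct.partner(i)
        run = [(i, j)]
        while True:
            ni, nj = run[-1][0] + 1, run[-1][1] - 1
            if ni < nj and struct.partner(ni) == nj:
                run.append((ni, nj))
            else:
                break
        in_stem.update(p for p, _ in run)
        positions = frozenset(p for pair in run for p in pair)
        elements.append(
            StructuralElement(
                kind=ElementKind.S, positions=positions, closing_pairs=tuple(run)
            )
        )

    # Loops: classify each closing pair by its directly enclosed branches.
    for i in opening:
        j = struct.partner(i)
        children, unpaired = _direct_children(struct, i, j)
        if len(children) == 0:
            kind = ElementKind.H
        elif len(children) == 1:
            (k, l) = children[0]
            if k == i + 1 and l == j - 1:
                continue  # stacked pair, absorbed into its stem
            left = k - i - 1
            right = j - l - 1
            kind = ElementKind.I if (left > 0 and right > 0) else ElementKind.B
        else:
            kind = ElementKind.M
        elements.append(
            StructuralElement(
                kind=kind,
                positions=frozenset(unpaired),
                closing_pairs=((i, j),) + tuple(children),
            )
        )

    return ElementDecomposition.from_elements(elements)
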