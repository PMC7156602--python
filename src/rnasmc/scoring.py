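"""The RNAsmc similarity score between two structure decompositions.

For each element kind u in {S, H, I, B, M} the score adds a positional
Jaccard term |u_p1 ∩ u_p2| / |u_p1 ∪ u_p2| and a count-ratio term
min(u_n1, u_n2) / max(u_n1, u_n2); the total SS lies in [0, 10].  Identical
structures with every kind present score 10; structures sharing no elements
score 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from .structure import ElementDecomposition, ElementKind

__all__ = ["ScoreResult", "rnasmc_score"]

EmptyKindConvention = Literal["zero", "one"]


@dataclass(frozen=True)
class ScoreResult:
    """SS score with its per-kind Jaccard and count-ratio terms."""

    SS: float
    per_kind_jaccard: Mapping[ElementKind, float]
    per_kind_count_ratio: Mapping[ElementKind, float]

    def __float__(self) -> float:
        return self.SS


def _jaccard(a: frozenset[int], b: frozenset[int], empty_value: float) -> float:
    union = a | b
    if not union:
        return empty_value
    return len(a & b) / len(union)


def _count_ratio(n1: int, n2: int, empty_value: float) -> float:
    if n1 == 0 and n2 == 0:
        return empty_value
    return min(n1, n2) / max(n1, n2)


def rnasmc_score(
    d1: ElementDecomposition,
    d2: ElementDecomposition,
    empty_kind_convention: EmptyKindConvention = "zero",
) -> ScoreResult:
    """Compute the RNAsmc score SS between two decompositions.

    Positions are compared as absolute 1-based indices (a point substitution
    preserves length, so wild-type/mutant comparisons always align).  A kind
    absent from both structures contributes 0 per term under the default
    ``"zero"`` convention, or 1 under ``"one"`` (which makes SS(A, A) = 10
    for every structure, including the fully unpaired one).

    The score is symmetric in its arguments.
    """
    if empty_kind_convention not in ("zero", "one"):
        raise ValueError(f"unknown empty-kind convention {empty_kind_convention!r}")
    empty_value = 0.0 if empty_kind_convention == "zero" else 1.0
    jaccard: dict[ElementKind, float] = {}
    ratio: dict[ElementKind, float] = {}
    for kind in ElementKind:
        jaccard[kind] = _jaccard(d1.u_p[kind], d2.u_p[kind], empty_value)
        ratio[kind] = _count_ratio(d1.u_n[kind], d2.u_n[kind], empty_value)
    ss = sum(jaccard.values()) + sum(ratio.values())
    return ScoreResult(SS=ss, per_kind_jaccard=jaccard, per_kind_count_ratio=ratio)
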