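"""SNPs, haplotypes, and the mutant / permuted sequence sets used by the
significance schemes.

Variant coordinates are transcript-relative and 1-based.  Only single-base
substitutions are handled; the reference allele is always checked against
the transcript before substitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .structure import RnaSequence, normalize_bases

__all__ = [
    "SnpVariant",
    "Haplotype",
    "ReferenceAlleleError",
    "apply_variants",
    "enumerate_point_mutants",
    "permute_nonfixed",
]

_BASES = "ACGU"


class ReferenceAlleleError(ValueError):
    """A variant's stated reference allele does not match the transcript."""


@dataclass(frozen=True)
class SnpVariant:
    """A single-nucleotide variant on a transcript (1-based position)."""

    rsid: str
    transcript_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", normalize_bases(self.ref))
        object.__setattr__(self, "alt", normalize_bases(self.alt))
        if self.position < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele not in _BASES:
                raise ValueError(f"{self.rsid}: allele {allele!r} is not a single base")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


@dataclass(frozen=True)
class Haplotype:
    """A series of SNPs carried together on one transcript."""

    transcript_id: str
    variants: tuple[SnpVariant, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("a haplotype needs at least one variant")
        positions = [v.position for v in self.variants]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("haplotype variants must have strictly increasing positions")
        for v in self.variants:
            if v.transcript_id != self.transcript_id:
                raise ValueError(
                    f"{v.rsid} is on {v.transcript_id}, not {self.transcript_id}"
                )

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.variants)


def apply_variants(seq: RnaSequence, variants: Sequence[SnpVariant]) -> RnaSequence:
    """Substitute each variant's alt allele into the sequence.

    The length is unchanged.  Raises :class:`ReferenceAlleleError` when a
    variant's ref allele disagrees with the transcript, and ``IndexError``
    for out-of-range positions.
    """
    bases = list(seq.bases)
    for v in variants:
        if not 1 <= v.position <= len(bases):
            raise IndexError(
                f"{v.rsid}: position {v.position} outside [1, {len(bases)}]"
            )
        found = bases[v.position - 1]
        if found != v.ref:
            raise ReferenceAlleleError(
                f"{v.rsid}: reference allele {v.ref} does not match transcript "
                f"base {found} at position {v.position}"
            )
        bases[v.position - 1] = v.alt
    return RnaSequence(seq.id, "".join(bases))


def invert_variants(variants: Sequence[SnpVariant]) -> list[SnpVariant]:
    """Swap ref and alt of each variant (undoes :func:`apply_variants`)."""
    return [
        SnpVariant(v.rsid, v.transcript_id, v.position, ref=v.alt, alt=v.ref)
        for v in variants
    ]


def enumerate_point_mutants(seq: RnaSequence) -> Iterator[RnaSequence]:
    """Yield all 3N single-base mutants of an N-base sequence.

    Deterministic order: position-major, alternative bases alphabetically.
    Every yielded sequence has Hamming distance 1 to the input.
    """
    bases = seq.bases
    for pos in range(len(bases)):
        for alt in _BASES:
            if alt == bases[pos]:
                continue
            yield RnaSequence(
                f"{seq.id}|{bases[pos]}{pos + 1}{alt}",
                bases[:pos] + alt + bases[pos + 1 :],
            )


def permute_nonfixed(
    seq: RnaSequence,
    fixed_sites: Iterable[int],
    rng: int | np.random.Generator,
) -> RnaSequence:
    """Uniformly permute the bases at all non-fixed positions.

    Bases at ``fixed_sites`` (1-based) are left untouched; the multiset of
    bases elsewhere is conserved.  ``rng`` is an integer seed or a numpy
    Generator (pass a Generator to draw several permutations from one
    stream).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    fixed = set(fixed_sites)
    n = len(seq)
    for p in fixed:
        if not 1 <= p <= n:
            raise IndexError(f"fixed site {p} outside [1, {n}]")
    free = [p for p in range(1, n + 1) if p not in fixed]
    shuffled = [seq.bases[p - 1] for p in free]
    order = rng.permutation(len(shuffled))
    bases = list(seq.bases)
    for target, src in zip(free, order):
        bases[target - 1] = shuffled[src]
    return RnaSequence(seq.id, "".join(bases))
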