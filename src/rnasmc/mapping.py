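"""Reposition SNPs onto transcripts from 25-nt flank reads.

dbSNP-style records carry the 25-nt sequence immediately upstream and
downstream of a SNP.  A SNP sits on a transcript exactly when both flanks
match the transcript on the same strand with their start coordinates 26 nt
apart: upstream occupies s_u .. s_u+24, the SNP base s_u+25, and the
downstream flank starts at s_u+26, so |s_u − s_d| = 26.  Matching is exact
by default (strict end-to-end placement); a Hamming mismatch tolerance is
available for parity with relaxed aligner settings.  Both strands are
searched — on the minus strand the reverse complements of the flanks appear
in swapped order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .structure import RnaSequence, normalize_bases

__all__ = ["FlankRead", "MappingRecord", "map_flanks", "reverse_complement"]

FLANK_LENGTH = 25
SNP_FLANK_DISTANCE = FLANK_LENGTH + 1  # 26: flank starts bracket the SNP base

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(bases: str) -> str:
    return normalize_bases(bases).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlankRead:
    """A SNP's 25-nt upstream/downstream flanks and its alleles."""

    rsid: str
    upstream: str
    downstream: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream", normalize_bases(self.upstream))
        object.__setattr__(self, "downstream", normalize_bases(self.downstream))
        object.__setattr__(self, "ref", normalize_bases(self.ref))
        object.__setattr__(self, "alt", normalize_bases(self.alt))
        for name in ("upstream", "downstream"):
            flank = getattr(self, name)
            if len(flank) != FLANK_LENGTH:
                raise ValueError(
                    f"{self.rsid}: {name} flank must be {FLANK_LENGTH} nt, "
                    f"got {len(flank)}"
                )


@dataclass(frozen=True)
class MappingRecord:
    """A SNP placed on a transcript by the flank-distance rule."""

    rsid: str
    transcript_id: str
    snp_position: int  # 1-based on the transcript
    strand: Literal["+", "-"]
    flank_start_distance: int  # s_u - s_d; |.| == 26 for accepted records


def _find_occurrences(haystack: str, needle: str, max_mismatch: int) -> list[int]:
    """1-based start positions of (near-)exact occurrences of needle."""
    if max_mismatch == 0:
        hits, start = [], 0
        while True:
            idx = haystack.find(needle, start)
            if idx == -1:
                return hits
            hits.append(idx + 1)
            start = idx + 1
    m = len(needle)
    return [
        s + 1
        for s in range(len(haystack) - m + 1)
        if sum(a != b for a, b in zip(haystack[s : s + m], needle)) <= max_mismatch
    ]


def map_flanks(
    transcripts: Sequence[RnaSequence],
    reads: Sequence[FlankRead],
    max_mismatch: int = 0,
) -> list[MappingRecord]:
    """Place each flank read on each transcript where the distance rule holds.

    Forward strand: upstream at s_u and downstream at s_d = s_u + 26 put the
    SNP at s_u + 25, where the transcript must carry the ref allele.  Minus
    strand: the reverse complement of the downstream flank appears first and
    that of the upstream flank 26 nt later; the transcript base between them
    must be the complement of the ref allele.  A read may map to several
    transcripts and a transcript may host several reads; multiple consistent
    placements within one transcript each produce a record.
    """
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids in input")
    records: list[MappingRecord] = []
    for t in transcripts:
        for read in reads:
            # forward strand
            up_hits = _find_occurrences(t.bases, read.upstream, max_mismatch)
            down_hits = set(_find_occurrences(t.bases, read.downstream, max_mismatch))
            for s_u in up_hits:
                s_d = s_u + SNP_FLANK_DISTANCE
                if s_d in down_hits:
                    pos = s_u + FLANK_LENGTH
                    if t[pos] == read.ref:
                        records.append(
                            MappingRecord(
                                rsid=read.rsid,
                                transcript_id=t.id,
                                snp_position=pos,
                                strand="+",
                                flank_start_distance=s_u - s_d,
                            )
                        )
            # minus strand: rc(downstream) ... SNP ... rc(upstream)
            rc_up_hits = _find_occurrences(
                t.bases, reverse_complement(read.upstream), max_mismatch
            )
            rc_down_hits = set(
                _find_occurrences(t.bases, reverse_complement(read.downstream), max_mismatch)
            )
            for s_u in rc_up_hits:
                s_d = s_u - SNP_FLANK_DISTANCE
                if s_d in rc_down_hits:
                    pos = s_d + FLANK_LENGTH
                    if t[pos] == reverse_complement(read.ref):
                        records.append(
                            MappingRecord(
                                rsid=read.rsid,
                                transcript_id=t.id,
                                snp_position=pos,
                                strand="-",
                                flank_start_distance=s_u - s_d,
                            )
                        )
    return records
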