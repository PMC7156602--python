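"""Readers and writers for the tool's interchange formats.

FASTA goes through Biopython; VCF through pysam; rectangular tables (variants,
flanks, haplotype blocks, results) are tab-separated files with a header row
and '#' comments, handled by pandas.  Vienna dot-bracket and CT structure
files are simple line formats written and parsed here.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import FlankRead, MappingRecord
from .structure import (
    RnaSequence,
    SecondaryStructure,
    StructureFormatError,
    parse_dotbracket,
    structure_from_pairs,
)
from .variants import Haplotype, SnpVariant

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_dotbracket",
    "write_dotbracket",
    "read_ct",
    "write_ct",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_vcf",
    "read_flanks_tsv",
    "write_flanks_tsv",
    "read_haplotypes_tsv",
    "write_mappings_tsv",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> list[RnaSequence]:
    return [RnaSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, sequences: Iterable[RnaSequence]) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------- Vienna dot-bracket

def read_dotbracket(path: str | os.PathLike) -> list[SecondaryStructure]:
    """Read Vienna records: '>id' line, sequence line, structure line.

    A trailing free-energy annotation on the structure line, e.g.
    ``(((...))) (-1.20)``, is ignored.
    """
    structures: list[SecondaryStructure] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureFormatError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise StructureFormatError(f"{path}: truncated record at line {i + 1}")
        seq_id = lines[i][1:].split()[0]
        seq = lines[i + 1].strip()
        db = lines[i + 2].split()[0]
        structures.append(parse_dotbracket(db, seq, seq_id=seq_id))
        i += 3
    return structures


def write_dotbracket(
    path: str | os.PathLike, structures: Iterable[SecondaryStructure]
) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.sequence.id}\n{s.sequence.bases}\n{s.dotbracket}\n")


# ------------------------------------------------------------------- CT

def read_ct(path: str | os.PathLike) -> list[SecondaryStructure]:
    """Read 6-column CT records (index, base, prev, next, pair, index).

    The header line starts with the base count and may carry an energy or
    title; multiple records per file are supported.
    """
    structures: list[SecondaryStructure] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    i = 0
    while i < len(lines):
        head = lines[i].split()
        try:
            n = int(head[0])
        except (ValueError, IndexError):
            raise StructureFormatError(f"{path}: bad CT header at line {i + 1}")
        title = head[1] if len(head) > 1 and not head[1].startswith(("dG", "ENERGY")) else "ct"
        bases: list[str] = []
        pairs: list[tuple[int, int]] = []
        for row in range(1, n + 1):
            if i + row >= len(lines):
                raise StructureFormatError(f"{path}: truncated CT record at line {i + 1}")
            cols = lines[i + row].split()
            if len(cols) < 6:
                raise StructureFormatError(
                    f"{path}: CT row needs 6 columns at line {i + row + 1}"
                )
            idx, base, pair = int(cols[0]), cols[1], int(cols[4])
            if idx != row:
                raise StructureFormatError(f"{path}: CT row index mismatch at line {i + row + 1}")
            bases.append(base)
            if pair > idx:
                pairs.append((idx, pair))
        seq = RnaSequence(title, "".join(bases))
        structures.append(structure_from_pairs(seq, pairs))
        i += n + 1
    return structures


def write_ct(path: str | os.PathLike, structures: Iterable[SecondaryStructure]) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.n} {s.sequence.id}\n")
            for i in range(1, s.n + 1):
                fh.write(
                    f"{i} {s.sequence.bases[i - 1]} {i - 1} "
                    f"{(i + 1) if i < s.n else 0} {s.partner(i)} {i}\n"
                )


# ------------------------------------------------------------------ TSV

def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


VARIANT_COLUMNS = ["rsid", "transcript_id", "position", "ref", "alt"]


def read_variants_tsv(path: str | os.PathLike) -> list[SnpVariant]:
    df = _read_tsv(path)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SnpVariant(
            rsid=row.rsid,
            transcript_id=row.transcript_id,
            position=int(row.position),
            ref=row.ref,
            alt=row.alt,
        )
        for row in df.itertuples()
    ]


def write_variants_tsv(path: str | os.PathLike, variants: Sequence[SnpVariant]) -> None:
    pd.DataFrame(
        [
            (v.rsid, v.transcript_id, v.position, v.ref, v.alt)
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | os.PathLike) -> list[SnpVariant]:
    """Minimal VCF subset: biallelic SNV records, CHROM read as transcript id."""
    import pysam

    variants: list[SnpVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # not an SNV
                variants.append(
                    SnpVariant(
                        rsid=rec.id or f"{rec.chrom}:{rec.pos}",
                        transcript_id=rec.chrom,
                        position=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                    )
                )
    return variants


FLANK_COLUMNS = ["rsid", "upstream", "downstream", "ref", "alt"]


def read_flanks_tsv(path: str | os.PathLike) -> list[FlankRead]:
    df = _read_tsv(path)
    missing = set(FLANK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FlankRead(
            rsid=row.rsid,
            upstream=row.upstream,
            downstream=row.downstream,
            ref=row.ref,
            alt=row.alt,
        )
        for row in df.itertuples()
    ]


def write_flanks_tsv(path: str | os.PathLike, reads: Sequence[FlankRead]) -> None:
    pd.DataFrame(
        [(r.rsid, r.upstream, r.downstream, r.ref, r.alt) for r in reads],
        columns=FLANK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path: str | os.PathLike) -> list[Haplotype]:
    """Read haplotype blocks: variant columns plus a ``block_id`` column."""
    df = _read_tsv(path)
    needed = {"block_id", *VARIANT_COLUMNS}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    haplotypes: list[Haplotype] = []
    for _, block in df.groupby("block_id", sort=False):
        block = block.sort_values("position", key=lambda s: s.astype(int))
        variants = tuple(
            SnpVariant(
                rsid=row.rsid,
                transcript_id=row.transcript_id,
                position=int(row.position),
                ref=row.ref,
                alt=row.alt,
            )
            for row in block.itertuples()
        )
        haplotypes.append(
            Haplotype(transcript_id=variants[0].transcript_id, variants=variants)
        )
    return haplotypes


def write_mappings_tsv(path: str | os.PathLike, records: Sequence[MappingRecord]) -> None:
    pd.DataFrame(
        [
            (r.rsid, r.transcript_id, r.snp_position, r.strand, r.flank_start_distance)
            for r in records
        ],
        columns=["rsid", "transcript_id", "snp_position", "strand", "flank_start_distance"],
    ).to_csv(path, sep="\t", index=False)


def write_sam_like(
    path: str | os.PathLike,
    records: Sequence[MappingRecord],
) -> None:
    """Minimal SAM-like text for inspection: read id, transcript, start, strand."""
    with open(path, "w") as fh:
        fh.write("# read_id\ttranscript\tsnp_position\tstrand\n")
        for r in records:
            fh.write(f"{r.rsid}\t{r.transcript_id}\t{r.snp_position}\t{r.strand}\n")
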