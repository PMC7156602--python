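"""Synthetic fixture generation: random transcripts, planted SNPs and
flank reads, with a truth table for recovery tests.

Everything downstream of SNP discovery is testable offline on these
fixtures: transcripts get optional planted complementary arms (guaranteeing
base pairs, hence at least one hairpin, under the built-in folder), SNPs are
planted at interior positions with correct reference alleles, and the
25-nt flank reads are cut from the planted context on a randomly chosen
strand.  All output is a deterministic function of the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import FLANK_LENGTH, FlankRead, reverse_complement
from .structure import RnaSequence
from .variants import SnpVariant
from . import io as rio

__all__ = ["FixtureSpec", "FixtureSet", "generate_fixtures", "random_sequence"]

_BASES = np.array(list("ACGU"))

# margin so both 25-nt flanks fit inside the transcript
_MIN_SNP_OFFSET = FLANK_LENGTH + 1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_transcripts: int = 10
    length_range: tuple[int, int] = (80, 160)
    gc_fraction: float = 0.5
    n_snps_per_transcript: int = 1
    plant_hairpin: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length range {self.length_range}")
        if self.n_snps_per_transcript > 0 and lo < 2 * _MIN_SNP_OFFSET + 8:
            raise ValueError(
                f"transcripts must be >= {2 * _MIN_SNP_OFFSET + 8} nt to plant "
                "SNPs with full flanks"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")


@dataclass
class FixtureSet:
    """Generated transcripts, variants, flank reads, and the truth table."""

    transcripts: list[RnaSequence]
    variants: list[SnpVariant]
    flanks: list[FlankRead]
    truth: pd.DataFrame = field(repr=False)

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write transcripts.fa, variants.tsv, flanks.tsv, truth.tsv."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "transcripts": os.path.join(outdir, "transcripts.fa"),
            "variants": os.path.join(outdir, "variants.tsv"),
            "flanks": os.path.join(outdir, "flanks.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        rio.write_fasta(paths["transcripts"], self.transcripts)
        rio.write_variants_tsv(paths["variants"], self.variants)
        rio.write_flanks_tsv(paths["flanks"], self.flanks)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def random_sequence(
    rng: np.random.Generator,
    length: int,
    gc_fraction: float = 0.5,
    seq_id: str = "random",
) -> RnaSequence:
    """A random transcript with the requested GC content in expectation."""
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # U
        ]
    )
    bases = rng.choice(_BASES, size=length, p=p)
    return RnaSequence(seq_id, "".join(bases))


def _plant_arms(rng: np.random.Generator, bases: str) -> str:
    """Overwrite a random window with a perfect stem-loop (arm, loop, rc-arm)
    so the built-in folder is guaranteed to find pairs."""
    arm_len, loop_len = 8, 4
    motif_len = 2 * arm_len + loop_len
    if len(bases) < motif_len:
        return bases
    arm = "".join(rng.choice(_BASES, size=arm_len))
    loop = "".join(rng.choice(_BASES, size=loop_len))
    motif = arm + loop + reverse_complement(arm)
    start = int(rng.integers(0, len(bases) - motif_len + 1))
    return bases[:start] + motif + bases[start + motif_len :]


def generate_fixtures(spec: FixtureSpec) -> FixtureSet:
    """Generate a reproducible synthetic dataset from a :class:`FixtureSpec`.

    SNPs are planted at distinct interior positions at least 26 nt from both
    transcript ends; each gets a flank read cut from the transcript on a
    random strand ('+' or '-', recorded in the truth table).  Minus-strand
    reads carry the reverse-complemented flanks in swapped roles, emulating
    a dbSNP record ascertained on the opposite strand.
    """
    rng = np.random.default_rng(spec.seed)
    transcripts: list[RnaSequence] = []
    variants: list[SnpVariant] = []
    flanks: list[FlankRead] = []
    truth_rows: list[dict] = []
    rs_counter = 1

    for t_index in range(spec.n_transcripts):
        lo, hi = spec.length_range
        length = int(rng.integers(lo, hi + 1))
        bases = random_sequence(rng, length, spec.gc_fraction).bases
        if spec.plant_hairpin:
            bases = _plant_arms(rng, bases)
        tid = f"TX{t_index + 1:04d}"
        transcript = RnaSequence(tid, bases)
        transcripts.append(transcript)

        if spec.n_snps_per_transcript == 0:
            continue
        candidates = np.arange(_MIN_SNP_OFFSET, length - FLANK_LENGTH + 1)
        n_snps = min(spec.n_snps_per_transcript, candidates.size)
        positions = sorted(
            int(p) for p in rng.choice(candidates, size=n_snps, replace=False)
        )
        for pos in positions:
            ref = transcript[pos]
            alt = str(rng.choice([b for b in "ACGU" if b != ref]))
            rsid = f"rs{rs_counter:06d}"
            rs_counter += 1
            variants.append(
                SnpVariant(
                    rsid=rsid, transcript_id=tid, position=pos, ref=ref, alt=alt
                )
            )
            up = bases[pos - 1 - FLANK_LENGTH : pos - 1]
            down = bases[pos : pos + FLANK_LENGTH]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                read = FlankRead(rsid, up, down, ref, alt)
            else:
                read = FlankRead(
                    rsid,
                    upstream=reverse_complement(down),
                    downstream=reverse_complement(up),
                    ref=reverse_complement(ref),
                    alt=reverse_complement(alt),
                )
            flanks.append(read)
            truth_rows.append(
                {
                    "rsid": rsid,
                    "transcript_id": tid,
                    "position": pos,
                    "strand": strand,
                    "ref": ref,
                    "alt": alt,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["rsid", "transcript_id", "position", "strand", "ref", "alt"],
    )
    return FixtureSet(
        transcripts=transcripts, variants=variants, flanks=flanks, truth=truth
    )
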