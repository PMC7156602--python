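"""Empirical significance of SNP- and haplotype-induced structure change.

Two permutation null models give an empirical p-value for the observed
wild-type/mutant RNAsmc score:

* **RS1** — flank permutation.  Holding the SNP sites fixed, the remaining
  transcript positions are shuffled; each shuffle yields a permuted-WT /
  permuted-MT pair (differing only at the SNP sites) whose score joins the
  background.  The default is 10,000 permutations.
* **RS2** — exhaustive single-point mutants.  Every one of the 3N possible
  single-base mutants of the N-base transcript is scored against the
  wild type; the observed variant's own mutant is part of the background.
  RS2 has no randomness and reruns bit-identically.

Both use the add-one left-tail rank p-value
``p = (1 + #{b <= SS_obs}) / (n_background + 1)``: a strongly disruptive
variant scores below nearly all background pairs and gets a small p.
Variants with p < 0.05 are conventionally called structure-altering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .folding import FoldingBackend
from .scoring import EmptyKindConvention, rnasmc_score
from .structure import RnaSequence, decompose
from .variants import (
    Haplotype,
    SnpVariant,
    apply_variants,
    enumerate_point_mutants,
    permute_nonfixed,
)

__all__ = ["SignificanceResult", "rs1", "rs2", "haplotype_effect", "empirical_p_value"]


@dataclass(frozen=True)
class SignificanceResult:
    """Observed score, its permutation background, and the empirical p."""

    method: Literal["RS1", "RS2"]
    observed_SS: float
    background: tuple[float, ...]
    p_value: float
    n_background: int
    rng_seed: int | None = None


def empirical_p_value(observed: float, background: Sequence[float]) -> float:
    """Add-one left-tail rank p: ``(1 + #{b <= observed}) / (n + 1)``.

    Monotone non-decreasing in ``observed`` for a fixed background; never 0.
    """
    n = len(background)
    le = sum(1 for b in background if b <= observed)
    return (1 + le) / (n + 1)


def _pair_score(
    wt: RnaSequence,
    mt: RnaSequence,
    backend: FoldingBackend,
    convention: EmptyKindConvention,
) -> float:
    return rnasmc_score(
        decompose(backend(wt)), decompose(backend(mt)), convention
    ).SS


def rs1(
    seq: RnaSequence,
    variants: Sequence[SnpVariant],
    n_perm: int = 10_000,
    rng_seed: int = 0,
    backend: FoldingBackend | None = None,
    empty_kind_convention: EmptyKindConvention = "zero",
    window: int | None = None,
) -> SignificanceResult:
    """Flank-permutation significance of one or several SNPs.

    The SNP sites stay fixed in every permutation; each background draw
    shuffles the remaining positions once and scores the resulting
    permuted-WT (ref alleles) against permuted-MT (alt alleles) — one shared
    permutation per pair, isolating the allele effect from shuffle noise.
    ``window`` restricts shuffling to positions within that many nt of a SNP
    site (default: the whole transcript is shuffled).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if backend is None:
        from .folding import nussinov_backend

        backend = nussinov_backend()
    sites = frozenset(v.position for v in variants)
    if not sites:
        raise ValueError("at least one variant is required")
    mt = apply_variants(seq, variants)
    observed = _pair_score(seq, mt, backend, empty_kind_convention)

    fixed = set(sites)
    if window is not None:
        in_window = {
            p
            for p in range(1, len(seq) + 1)
            if all(abs(p - s) > window for s in sites)
        }
        fixed |= in_window  # outside-window positions never move

    rng = np.random.default_rng(rng_seed)
    background: list[float] = []
    for _ in range(n_perm):
        perm_wt = permute_nonfixed(seq, fixed, rng)
        perm_mt = apply_variants(perm_wt, variants)
        background.append(_pair_score(perm_wt, perm_mt, backend, empty_kind_convention))

    return SignificanceResult(
        method="RS1",
        observed_SS=observed,
        background=tuple(background),
        p_value=empirical_p_value(observed, background),
        n_background=n_perm,
        rng_seed=rng_seed,
    )


def rs2(
    seq: RnaSequence,
    variant: SnpVariant,
    backend: FoldingBackend | None = None,
    empty_kind_convention: EmptyKindConvention = "zero",
) -> SignificanceResult:
    """Exhaustive single-point-mutant significance of one SNP.

    The background holds the 3N scores of the wild type against every
    possible single-base mutant, including the observed variant's own
    mutant (which therefore always ties the observed score).
    """
    if backend is None:
        from .folding import nussinov_backend

        backend = nussinov_backend()
    wt_decomp = decompose(backend(seq))
    mt = apply_variants(seq, [variant])
    observed = rnasmc_score(
        wt_decomp, decompose(backend(mt)), empty_kind_convention
    ).SS
    background = [
        rnasmc_score(wt_decomp, decompose(backend(m)), empty_kind_convention).SS
        for m in enumerate_point_mutants(seq)
    ]
    assert len(background) == 3 * len(seq)
    return SignificanceResult(
        method="RS2",
        observed_SS=observed,
        background=tuple(background),
        p_value=empirical_p_value(observed, background),
        n_background=len(background),
        rng_seed=None,
    )


def haplotype_effect(
    seq: RnaSequence,
    hap: Haplotype,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    backend: FoldingBackend | None = None,
    empty_kind_convention: EmptyKindConvention = "zero",
    window: int | None = None,
) -> SignificanceResult:
    """Combined structural effect of a haplotype (all alleles applied at once).

    The mutant carries every haplotype allele simultaneously; significance
    follows the RS1 permutation scheme with all haplotype positions held
    fixed.  A one-SNP haplotype is identical to :func:`rs1` of that SNP.
    """
    return rs1(
        seq,
        hap.variants,
        n_perm=n_perm,
        rng_seed=rng_seed,
        backend=backend,
        empty_kind_convention=empty_kind_convention,
        window=window,
    )
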