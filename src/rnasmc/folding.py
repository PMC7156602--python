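"""Folding backends: a built-in deterministic pair-maximization folder and
adapters for external thermodynamic folders.

The structural-disruption method only consumes secondary structures; it is
agnostic to how they were predicted.  The built-in backend is a Nussinov-style
dynamic program maximizing the number of canonical pairs (AU, GC and GU
wobble) subject to a minimum hairpin size, with a fixed traceback order so
results are bit-reproducible.  External folders plug in through the
:class:`FoldingBackend` contract (any callable producing a
:class:`~rnasmc.structure.SecondaryStructure` for an input sequence).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from .structure import (
    RnaSequence,
    SecondaryStructure,
    StructureFormatError,
    parse_dotbracket,
    structure_from_pairs,
)

__all__ = [
    "FoldingBackend",
    "fold_nussinov",
    "fold_external",
    "nussinov_backend",
    "BackendConfigurationError",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# canonical + wobble: AU, UA, GC, CG, GU, UG
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = True


class BackendConfigurationError(RuntimeError):
    """Raised when an external folding backend is missing or misconfigured."""


@dataclass(frozen=True)
class FoldingBackend:
    """A named, deterministic sequence -> structure function."""

    name: str
    fold: Callable[[RnaSequence], SecondaryStructure]

    def __call__(self, seq: RnaSequence) -> SecondaryStructure:
        struct = self.fold(seq)
        if struct.sequence.bases != seq.bases:
            raise StructureFormatError(
                f"backend {self.name!r} returned a structure for a different sequence"
            )
        return struct


@njit(cache=True)
def _nussinov_fill(enc, pairable, min_hairpin):  # pragma: no cover - jitted
    n = enc.size
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_hairpin):
                if pairable[enc[k], enc[j]]:
                    left = dp[i, k - 1] if k > i else 0
                    inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    v = left + inner + 1
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _traceback(dp, enc, min_hairpin: int) -> list[tuple[int, int]]:
    """Deterministic traceback: prefer leaving j unpaired, then the smallest
    admissible pairing partner k."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, enc.size - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_hairpin:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_hairpin):
            if not _PAIRABLE[enc[k], enc[j]]:
                continue
            left = dp[i, k - 1] if k > i else 0
            inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
            if left + inner + 1 == dp[i, j]:
                pairs.append((k + 1, j + 1))  # to 1-based
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                break
    return pairs


def fold_nussinov(seq: RnaSequence, min_hairpin: int = 3) -> SecondaryStructure:
    """Fold by maximizing canonical/wobble pair count (Nussinov DP).

    Pairs (i, j) must satisfy j - i > ``min_hairpin`` (default 3, the steric
    minimum hairpin size).  Ties are broken deterministically: leave the
    rightmost base unpaired first, otherwise pair it with the smallest
    admissible partner.
    """
    if min_hairpin < 0:
        raise ValueError("min_hairpin must be non-negative")
    enc = np.array([_BASE_CODE[b] for b in seq.bases], dtype=np.uint8)
    if enc.size - 1 <= min_hairpin:
        return structure_from_pairs(seq, [])
    dp = _nussinov_fill(enc, _PAIRABLE, min_hairpin)
    pairs = _traceback(dp, enc, min_hairpin)
    return structure_from_pairs(seq, pairs)


def nussinov_backend(min_hairpin: int = 3) -> FoldingBackend:
    """The built-in pair-maximization backend as a :class:`FoldingBackend`."""
    return FoldingBackend(
        name=f"nussinov(min_hairpin={min_hairpin})",
        fold=lambda seq: fold_nussinov(seq, min_hairpin=min_hairpin),
    )


def fold_external(seq: RnaSequence, backend: FoldingBackend) -> SecondaryStructure:
    """Fold through an external backend, validating the returned structure."""
    if not isinstance(backend, FoldingBackend) or not backend.name:
        raise BackendConfigurationError("a named FoldingBackend is required")
    return backend(seq)


def ct_backend(ct_path: str) -> FoldingBackend:
    """Backend serving pre-computed structures from a CT file.

    Useful for consuming the output of thermodynamic folders that write CT;
    the requested sequence must match one of the file's records.
    """
    from .io import read_ct  # local import to avoid a cycle

    structures = {s.sequence.bases: s for s in read_ct(ct_path)}

    def fold(seq: RnaSequence) -> SecondaryStructure:
        try:
            found = structures[seq.bases]
        except KeyError:
            raise BackendConfigurationError(
                f"no structure for sequence {seq.id!r} in {ct_path}"
            ) from None
        return SecondaryStructure(
            sequence=seq, dotbracket=found.dotbracket, pair_table=found.pair_table
        )

    return FoldingBackend(name=f"ct:{ct_path}", fold=fold)


def viennarna_backend(executable: str = "RNAfold") -> FoldingBackend:
    """Adapter around the ViennaRNA ``RNAfold`` command-line folder.

    Opt-in: requires the executable on PATH.  Thermodynamic minimum-free-
    energy structures replace the built-in pair-maximization fold.
    """
    if shutil.which(executable) is None:
        raise BackendConfigurationError(f"{executable!r} not found on PATH")

    def fold(seq: RnaSequence) -> SecondaryStructure:
        proc = subprocess.run(
            [executable, "--noPS"],
            input=f">{seq.id}\n{seq.bases}\n",
            capture_output=True,
            text=True,
            check=True,
        )
        # output: >id / sequence / dotbracket ( energy )
        db = ""
        for line in proc.stdout.splitlines():
            token = line.split(" ")[0]
            if token and set(token) <= set("()."):
                db = token
                break
        if len(db) != len(seq):
            raise StructureFormatError(
                f"could not parse RNAfold output for {seq.id!r}"
            )
        return parse_dotbracket(db, seq.bases, seq_id=seq.id)

    return FoldingBackend(name=f"vienna:{executable}", fold=fold)
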