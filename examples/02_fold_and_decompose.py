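"""Fold a sequence with the built-in folder and decompose the structure.

The built-in backend maximizes canonical/wobble pairs (Nussinov dynamic
programming) with a deterministic traceback, so the same sequence always
gives the same structure.
"""

from rnasmc import RnaSequence, decompose, fold_nussinov

seq = RnaSequence("demo", "GGGGAAAACCCCAAGGGAAACCC")
struct = fold_nussinov(seq)
print(seq.bases)
print(struct.dotbracket)

d = decompose(struct)
print("element counts:", {str(k): v for k, v in d.u_n.items()})
print("hairpin positions:", sorted(d.u_p[next(k for k in d.u_p if str(k) == 'H')]))
print("S = stems (paired bases), H/I/B/M = hairpin/interior/bulge/multibranch loops.")
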