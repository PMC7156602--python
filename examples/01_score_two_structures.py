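"""Compare two secondary structures with the RNAsmc score.

A wild-type stem-hairpin is compared against a shortened variant of itself:
the score sums, over the five element kinds, a positional Jaccard term and
a count-ratio term, so partial stem overlap shows up directly.
"""

from rnasmc import decompose, parse_dotbracket, rnasmc_score

wt = parse_dotbracket("(((...)))", "GGGAAACCC", seq_id="wt")
mt = parse_dotbracket("((.....))", "GGGAAACCC", seq_id="mt")

result = rnasmc_score(decompose(wt), decompose(mt))
print(f"SS = {result.SS:.4f}   (0 = no shared elements, 10 = identical)")
for kind in result.per_kind_jaccard:
    print(
        f"  {kind}: jaccard={result.per_kind_jaccard[kind]:.4f} "
        f"count_ratio={result.per_kind_count_ratio[kind]:.4f}"
    )
print("The stem term drops because the variant keeps only 4 of 6 stem bases;")
print("hairpin positions overlap partially (3 of 5), and I/B/M are absent.")
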