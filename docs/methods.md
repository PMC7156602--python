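# Methods

## Structure model and loop decomposition

A secondary structure is a nested (pseudoknot-free) set of base pairs over
an RNA sequence, held as a 1-based pair table plus its dot-bracket string.
Pseudoknots are rejected at construction rather than silently broken: the
similarity score presumes a unique nested loop decomposition, which crossing
pairs do not have.

The decomposition follows the standard loop taxonomy. For each closing pair
(i, j) the directly enclosed branch pairs determine the element:

* 0 branches — hairpin loop (H), positions i+1 … j−1;
* 1 branch stacked flush against (i, j) — part of a stem, no loop;
* 1 branch with unpaired bases on exactly one side — bulge loop (B);
* 1 branch with unpaired bases on both sides — interior loop (I);
* ≥2 branches — multibranch loop (M), all loop-interior unpaired positions.

Stems (S) are maximal runs of consecutively stacked pairs; a lone pair is a
stem of length 1, so every paired base belongs to exactly one stem. Stem
position sets include both strands' paired bases; loop position sets hold
only unpaired bases. The five kinds therefore partition all classified
positions, which the tests check directly. Exterior (outside every pair)
bases belong to no element: adding a sixth exterior kind would change the
score's maximum away from 10.

Degenerate loops with zero unpaired bases can occur — a multiloop whose
helices abut directly, or the sterically impossible but parseable `()`.
These are counted as elements (they are real junctions) while contributing
nothing to the position sets.

## The similarity score

For each kind u, two structures contribute a positional Jaccard term
|u_p1 ∩ u_p2| / |u_p1 ∪ u_p2| and a count-ratio term
min(u_n1, u_n2) / max(u_n1, u_n2); SS is the sum of the ten terms and lies
in [0, 10]. Positions are compared as absolute indices — a point
substitution preserves length, so wild-type/mutant structures always align;
the definition extends to unequal lengths for robustness.

A kind absent from both structures is a 0/0 case in both terms. The default
convention scores it 0, which makes both calibration anchors exactly
realizable: identical structures containing every kind score 10, and a
folded structure against a fully unpaired one scores 0. The price is that
identical structures *lacking* some kinds self-score below 10 (a pure
stem-hairpin fold self-scores 4). The alternative `"one"` convention
(both-empty → 1) restores SS(A, A) = 10 universally but makes the
no-overlap score 3 rather than 0 for a typical stem-hairpin versus an
unpaired string. The two desiderata cannot both hold under one convention;
`zero` is the default and `one` is a flag on every scoring entry point.
Long natural transcripts almost always contain all five kinds, where the
distinction vanishes.

## Folding

The method consumes structures and is agnostic to the folder. The built-in
backend is Nussinov-style pair maximization over {AU, UA, GC, CG, GU, UG}
with a minimum hairpin size of 3 nt (the steric minimum), chosen because it
is deterministic, dependency-free, and fast enough to power tens of
thousands of background folds. Ties in the dynamic program are broken
deterministically — leave the rightmost base unpaired first, otherwise pair
it with the smallest admissible partner — so folds are bit-reproducible.
The DP fill is numba-compiled; an 80-nt fold takes ~0.5 ms.

Pair maximization is not a thermodynamic model: it has no stacking energies,
tends to produce more, shorter helices than a free-energy folder, and its
structures should not be read as MFE predictions. External folders plug in
through the `FoldingBackend` contract; adapters are provided for CT files
and for ViennaRNA's `RNAfold` executable, and any returned structure is
validated (sequence identity, nestedness) before use.

## Significance schemes

**RS1 (flank permutation).** Holding the SNP site(s) fixed, all remaining
positions are shuffled uniformly; each shuffle is applied once and shared by
the permuted-WT (ref alleles) and permuted-MT (alt alleles), which differ
only at the fixed sites — isolating the allele effect from shuffle noise.
Both are folded and scored; 10,000 permutations by default (tests and
examples scale this down to 200 for speed, stated wherever used). The
shuffle spans the whole transcript by default; a `window` parameter
restricts it to positions within W nt of a SNP site for a local null.

**RS2 (exhaustive mutants).** The background is the score of the wild type
against each of the 3N single-base mutants, enumerated
position-major/alphabetically. The observed variant's own mutant stays in
the background, so its score always ties itself and p ≥ 2/(3N + 1). RS2 is
exhaustive and fully deterministic.

**p-value.** Both schemes use the add-one left-tail rank
p = (1 + #{b ≤ SS_obs}) / (n + 1): a disruptive variant scores below nearly
all background pairs, leaving few b ≤ SS_obs. The add-one correction keeps
p in (0, 1] and is standard for permutation tests. Under an exchangeable
null (the observed pair itself a random permutation) the p-values are
uniform on (0, 1], which the test suite verifies with a Kolmogorov–Smirnov
check at α = 0.01 over 200 replicates. The conventional significance
threshold is p < 0.05; no multiple-testing correction is applied by default.

**Haplotypes.** A block's alleles are applied simultaneously and assessed by
RS1 with all block positions fixed; a one-SNP block reduces exactly to the
single-SNP case. Haplotype inference from population genotypes is out of
scope — blocks are accepted as input lists.

## SNP repositioning

dbSNP-style records carry 25-nt flanks on each side of a SNP. On a
transcript, an upstream match starting at s_u and a downstream match at
s_d = s_u + 26 bracket exactly one base — the SNP — at s_u + 25, where the
transcript must carry the ref allele (its complement on the minus strand,
where the reverse-complemented flanks appear in swapped order). Matching is
exact substring search by default, reproducing a strict end-to-end
alignment; `max_mismatch` relaxes it with Hamming tolerance. Any |s_u − s_d|
≠ 26 (e.g. an indel between the flanks) is rejected. Multiple consistent
placements each produce a record; ambiguity is reported, never dropped.

## Synthetic data

The fixture generator emulates the shape of the real inputs: random
transcripts (uniform length in a range, configurable GC content, default
0.5), optionally a planted 8-bp complementary arm pair (guaranteeing base
pairs — hence at least one hairpin — under the built-in folder), SNPs at
interior positions ≥26 nt from both ends with correct reference alleles,
and flank reads cut from the planted context on a random strand. A truth
table makes recovery exact to check. Defaults (10–100 transcripts of
80–160 nt, one SNP each) keep every test desk-scale.

What the generator does **not** emulate: real lncRNA length (hundreds to
thousands of nt), thermodynamic structure, linkage structure among SNPs,
sequencing error in flanks, and genome-to-transcript coordinate complexity
(splicing). Passing tests therefore demonstrate the algorithms' correctness
and calibration, not biological conclusions about any particular transcript.

## Numerical and design choices

* All coordinates are 1-based and inclusive throughout.
* T is normalized to U on every input path (sequences, alleles, flanks), so
  DNA-convention dbSNP records align to RNA transcripts.
* Scores print to 4 decimal places; full precision is kept internally.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; RS2 and the folder have no randomness at all.
* Degenerate inputs: an empty variant list is the identity for
  `apply_variants` but an error for a `Haplotype`; `permute_nonfixed` with
  all sites fixed returns the input; folding a sequence shorter than the
  minimum hairpin span returns the unpaired structure.
* The pipeline derives per-variant RS1 seeds as `seed + index`, so a run is
  reproducible from its config while variants get independent streams.

## Known limitations

* Pair maximization exaggerates pairing relative to thermodynamic folders;
  absolute SS values depend on the folder choice, and comparisons should
  hold the backend fixed.
* Only single-base substitutions are supported (no indels or MNVs).
* Pseudoknots, suboptimal ensembles, and base-pair probabilities are out of
  scope.
* The RS1 null permutes whole-transcript composition; for long transcripts
  with strongly non-uniform local composition the `window` option gives a
  more local null, at the cost of an arbitrary window choice.
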