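"""Dot-bracket parsing and loop decomposition."""

import pytest

from rnasmc import ElementKind, decompose, parse_dotbracket
from rnasmc.structure import StructureFormatError, structure_from_pairs, RnaSequence

from oracles import all_dotbracket_strings, brute_force_decomposition

K = ElementKind


def test_parse_matches_hand_derived_pairs():
    s = parse_dotbracket("(((...)))", "GGGAAACCC")
    assert s.pairs() == [(1, 9), (2, 8), (3, 7)]
    assert parse_dotbracket("...", "AAA").pairs() == []


@pytest.mark.parametrize(
    "db,seq",
    [
        ("((.", "GGC"),  # unmatched '('
        (".))", "GCC"),  # unmatched ')'
        ("(((...)))", "GGAACC"),  # length mismatch
        ("((x...)))", "GGGAAACCC"),  # stray character
    ],
)
def test_parse_rejects_malformed_input(db, seq):
    with pytest.raises(StructureFormatError):
        parse_dotbracket(db, seq)


def test_sequence_normalization_and_validation():
    assert RnaSequence("x", "acgt").bases == "ACGU"
    with pytest.raises(ValueError):
        RnaSequence("x", "ACGX")
    with pytest.raises(ValueError):
        RnaSequence("x", "")


def test_pseudoknots_are_rejected():
    seq = RnaSequence("pk", "GGGGAAAACCCC")
    with pytest.raises(StructureFormatError, match="pseudoknot"):
        structure_from_pairs(seq, [(1, 8), (5, 12)])


@pytest.mark.parametrize(
    "db,expected_counts,expected_sets",
    [
        (
            "(((...)))",
            {K.S: 1, K.H: 1, K.I: 0, K.B: 0, K.M: 0},
            {K.S: {1, 2, 3, 7, 8, 9}, K.H: {4, 5, 6}},
        ),
        (
            "((..((...))))",
            {K.S: 2, K.H: 1, K.B: 1, K.I: 0, K.M: 0},
            {K.B: {3, 4}, K.H: {7, 8, 9}},
        ),
        (
            ".........",
            {K.S: 0, K.H: 0, K.I: 0, K.B: 0, K.M: 0},
            {k: set() for k in K},
        ),
    ],
)
def test_decompose_hand_derived_examples(db, expected_counts, expected_sets):
    d = decompose(parse_dotbracket(db, "A" * len(db)))
    assert dict(d.u_n) == expected_counts
    for kind, positions in expected_sets.items():
        assert set(d.u_p[kind]) == positions


def test_all_five_kinds_present_in_reference_structure(all_kinds_structure):
    d = decompose(all_kinds_structure)
    assert all(d.u_n[k] >= 1 for k in K)


def test_exterior_bases_belong_to_no_element():
    d = decompose(parse_dotbracket("..(((...)))..", "A" * 13))
    classified = set().union(*d.u_p.values())
    assert classified == set(range(3, 12))  # 1,2,12,13 are exterior


def test_decompose_matches_bruteforce_on_short_strings():
    """Spot-check against the exhaustive classifier on all strings up to 8 nt
    (the full length-10 sweep runs with the acceptance checks)."""
    for db in all_dotbracket_strings(8):
        d = decompose(parse_dotbracket(db, "A" * len(db)))
        u_p, u_n = brute_force_decomposition(db)
        assert {k.value: v for k, v in d.u_n.items()} == u_n, db
        assert {k.value: set(v) for k, v in d.u_p.items()} == {
            k: set(v) for k, v in u_p.items()
        }, db


def test_partition_invariants_on_folded_fixtures(small_fixture_set, backend):
    """Paired bases live in exactly one stem; loop sets are pairwise disjoint."""
    for transcript in small_fixture_set.transcripts:
        struct = backend(transcript)
        d = decompose(struct)
        paired = {p for i, j in struct.pairs() for p in (i, j)}
        stem_positions = [p for e in d.elements if e.kind is K.S for p in e.positions]
        assert sorted(stem_positions) == sorted(paired)  # exact cover, no overlap
        loop_sets = [d.u_p[k] for k in (K.H, K.I, K.B, K.M)]
        for a in range(len(loop_sets)):
            assert not (loop_sets[a] & d.u_p[K.S])
            for b in range(a + 1, len(loop_sets)):
                assert not (loop_sets[a] & loop_sets[b])


def test_decompose_is_deterministic(all_kinds_structure):
    d1 = decompose(all_kinds_structure)
    d2 = decompose(all_kinds_structure)
    assert d1.elements == d2.elements
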