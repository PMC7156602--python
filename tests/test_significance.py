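"""RS1 / RS2 empirical significance and haplotype combined effects."""

import pytest

from rnasmc import Haplotype, RnaSequence, SnpVariant, haplotype_effect, rs1, rs2
from rnasmc.significance import empirical_p_value


def _v(pos, ref, alt, rsid="rs1", tid="t"):
    return SnpVariant(rsid, tid, pos, ref, alt)


# planted GC helix with an unpairable all-A tail: tail substitutions to C
# cannot gain a pair, so the fold is unchanged
NEUTRAL_SEQ = RnaSequence("t", "GGGGAAAACCCCAAAAA")


def test_add_one_rank_formula():
    # observed strictly below 19 background scores -> p = 1/20
    assert empirical_p_value(1.0, [2.0] * 19) == pytest.approx(0.05)
    # observed at the maximum -> p = 1
    assert empirical_p_value(10.0, [3.0, 7.0, 10.0]) == 1.0
    # monotone non-decreasing in the observed score
    bg = [1.0, 2.0, 5.0, 7.0]
    ps = [empirical_p_value(s, bg) for s in (0.5, 1.5, 6.0, 8.0)]
    assert ps == sorted(ps)


def test_rs1_neutral_variant_has_p_one(backend):
    """A fold-preserving variant sits at the score maximum, hence p = 1.

    The guaranteed maximum for identical structures is 10 under the "one"
    empty-kind convention; under the default "zero" convention an identical
    pair lacking some element kinds scores below 10 (here 4: only stems and
    hairpins are present), so the observed score equals the wild type's
    self-score instead.
    """
    res = rs1(NEUTRAL_SEQ, [_v(17, "A", "C")], n_perm=30, rng_seed=1,
              backend=backend, empty_kind_convention="one")
    assert res.observed_SS == 10.0
    assert res.p_value == 1.0
    assert res.method == "RS1" and res.n_background == 30

    from rnasmc import decompose, rnasmc_score

    res0 = rs1(NEUTRAL_SEQ, [_v(17, "A", "C")], n_perm=10, rng_seed=1, backend=backend)
    wt_d = decompose(backend(NEUTRAL_SEQ))
    assert res0.observed_SS == rnasmc_score(wt_d, wt_d).SS == 4.0


def test_rs1_is_seed_reproducible(backend):
    a = rs1(NEUTRAL_SEQ, [_v(6, "A", "U")], n_perm=25, rng_seed=7, backend=backend)
    b = rs1(NEUTRAL_SEQ, [_v(6, "A", "U")], n_perm=25, rng_seed=7, backend=backend)
    assert a.background == b.background and a.p_value == b.p_value
    c = rs1(NEUTRAL_SEQ, [_v(6, "A", "U")], n_perm=25, rng_seed=8, backend=backend)
    assert a.background != c.background


def test_rs1_rejects_bad_parameters(backend):
    with pytest.raises(ValueError):
        rs1(NEUTRAL_SEQ, [_v(17, "A", "C")], n_perm=0, backend=backend)
    with pytest.raises(ValueError):
        rs1(NEUTRAL_SEQ, [], n_perm=10, backend=backend)


def test_rs1_window_keeps_distant_positions_fixed(backend):
    """With a small window, only bases near the SNP may move; the p-value
    machinery still runs end to end."""
    res = rs1(
        NEUTRAL_SEQ, [_v(17, "A", "C")], n_perm=10, rng_seed=3,
        backend=backend, window=4,
    )
    assert 0.0 < res.p_value <= 1.0


def test_rs2_background_is_exactly_3n(backend):
    seq = RnaSequence("t", "GAUCC")
    res = rs2(seq, _v(2, "A", "G"), backend=backend)
    assert res.n_background == 15 == 3 * len(seq)
    assert res.method == "RS2" and res.rng_seed is None


def test_rs2_reruns_bit_identically(backend):
    seq = RnaSequence("t", "GGGGAAAACCCCAAAAA")
    a = rs2(seq, _v(6, "A", "U"), backend=backend)
    b = rs2(seq, _v(6, "A", "U"), backend=backend)
    assert a.background == b.background
    assert a.p_value == b.p_value


def test_rs2_unpairable_sequence_gives_p_one(backend):
    """All-A 6-mer: no mutant can pair under the built-in folder, every
    score ties, so the rank p-value is 1."""
    res = rs2(RnaSequence("a6", "AAAAAA"), _v(3, "A", "C", tid="a6"), backend=backend)
    assert set(res.background) == {0.0}
    assert res.observed_SS == 0.0
    assert res.p_value == 1.0


def test_rs2_unique_minimum_ties_only_itself(backend):
    """A variant whose mutant scores strictly below every other background
    entry ties only its own background copy: p = 2/(3N+1)."""
    seq = RnaSequence("u", "GUUACUAUUCCCCCGGUUGUAAGAAGCUGG")
    res = rs2(seq, _v(4, "A", "U", tid="u"), backend=backend)
    below = sum(1 for b in res.background if b <= res.observed_SS)
    assert below == 1  # only its own copy
    assert res.p_value == pytest.approx(2 / (3 * len(seq) + 1))


def test_haplotype_of_one_snp_equals_rs1(backend):
    v = _v(6, "A", "U")
    hap = Haplotype("t", (v,))
    a = haplotype_effect(NEUTRAL_SEQ, hap, n_perm=20, rng_seed=5, backend=backend)
    b = rs1(NEUTRAL_SEQ, [v], n_perm=20, rng_seed=5, backend=backend)
    assert a == b


def test_haplotype_in_unpairable_context_is_neutral(backend):
    hap = Haplotype("t", (_v(16, "A", "C", rsid="a"), _v(17, "A", "C", rsid="b")))
    res = haplotype_effect(NEUTRAL_SEQ, hap, n_perm=20, rng_seed=2,
                           backend=backend, empty_kind_convention="one")
    assert res.observed_SS == 10.0
    assert res.p_value == 1.0
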