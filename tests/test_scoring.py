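"""The RNAsmc similarity score."""

import pytest
from hypothesis import given, settings, strategies as st

from rnasmc import ElementKind, decompose, parse_dotbracket, rnasmc_score
from rnasmc.structure import ElementDecomposition, StructuralElement
from rnasmc.simulate import random_sequence
from rnasmc import fold_nussinov

import numpy as np

K = ElementKind


def _decomp(pairs_by_kind):
    """Build a decomposition from {kind: [position-sets]}."""
    elements = [
        StructuralElement(kind, frozenset(positions), ())
        for kind, sets in pairs_by_kind.items()
        for positions in sets
    ]
    return ElementDecomposition.from_elements(elements)


def test_hand_evaluated_example():
    """S-term 4/6 + 1, H-term 1 + 1, others empty -> SS = 3.6667."""
    d1 = _decomp({K.S: [{1, 2, 3, 7, 8, 9}], K.H: [{4, 5, 6}]})
    d2 = _decomp({K.S: [{1, 2, 8, 9}], K.H: [{4, 5, 6}]})
    res = rnasmc_score(d1, d2)
    assert res.SS == pytest.approx(4 / 6 + 1 + 1 + 1)
    assert round(res.SS, 4) == 3.6667
    assert res.per_kind_jaccard[K.S] == pytest.approx(4 / 6)
    assert res.per_kind_count_ratio[K.S] == 1.0


def test_identity_scores_ten_with_all_kinds(all_kinds_structure):
    d = decompose(all_kinds_structure)
    assert rnasmc_score(d, d).SS == 10.0


def test_folded_vs_unpaired_scores_zero():
    folded = decompose(parse_dotbracket("(((...)))", "G" * 9))
    unpaired = decompose(parse_dotbracket("." * 9, "G" * 9))
    assert rnasmc_score(folded, unpaired).SS == 0.0


def test_empty_kind_conventions():
    """Two structureless decompositions: 0 under "zero", 10 under "one"."""
    empty = _decomp({})
    assert rnasmc_score(empty, empty, "zero").SS == 0.0
    assert rnasmc_score(empty, empty, "one").SS == 10.0
    with pytest.raises(ValueError):
        rnasmc_score(empty, empty, "maybe")


def test_identity_is_ten_under_one_convention_for_any_structure():
    d = decompose(parse_dotbracket("(((...)))", "G" * 9))  # no I/B/M elements
    assert rnasmc_score(d, d, "one").SS == 10.0
    assert rnasmc_score(d, d, "zero").SS < 10.0  # absent kinds contribute 0


def test_symmetry_and_bounds_on_random_folded_pairs(backend):
    rng = np.random.default_rng(5)
    for i in range(50):
        a = decompose(backend(random_sequence(rng, 60, seq_id=f"a{i}")))
        b = decompose(backend(random_sequence(rng, 60, seq_id=f"b{i}")))
        ab = rnasmc_score(a, b).SS
        ba = rnasmc_score(b, a).SS
        assert ab == ba
        assert 0.0 <= ab <= 10.0


def test_removing_all_overlap_of_one_kind_never_increases_score():
    base = {K.S: [{1, 2, 9, 10}], K.H: [{4, 5, 6}], K.B: [{3}]}
    d1 = _decomp(base)
    d2_same = _decomp(base)
    # strip the bulge from one side: jaccard B drops 1->0, ratio 1->0
    degraded = _decomp({K.S: [{1, 2, 9, 10}], K.H: [{4, 5, 6}]})
    assert rnasmc_score(d1, degraded).SS <= rnasmc_score(d1, d2_same).SS


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    counts1=st.lists(st.integers(0, 3), min_size=5, max_size=5),
    counts2=st.lists(st.integers(0, 3), min_size=5, max_size=5),
    data=st.data(),
)
def test_score_bounds_and_symmetry_property(counts1, counts2, data):
    """SS is symmetric and within [0, 10] for arbitrary decompositions."""

    def build(counts):
        by_kind = {}
        offset = 1
        for kind, n in zip(K, counts):
            sets = []
            for _ in range(n):
                size = data.draw(st.integers(1, 4))
                start = data.draw(st.integers(1, 30))
                sets.append(set(range(start, start + size)))
                offset += size
            by_kind[kind] = sets
        return _decomp(by_kind)

    d1, d2 = build(counts1), build(counts2)
    r12 = rnasmc_score(d1, d2)
    r21 = rnasmc_score(d2, d1)
    assert r12.SS == pytest.approx(r21.SS)
    assert 0.0 <= r12.SS <= 10.0
    for k in K:
        assert 0.0 <= r12.per_kind_jaccard[k] <= 1.0
        assert 0.0 <= r12.per_kind_count_ratio[k] <= 1.0
    assert r12.SS == pytest.approx(
        sum(r12.per_kind_jaccard.values()) + sum(r12.per_kind_count_ratio.values())
    )
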