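"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's algorithms: loop classification works
position by position through exhaustive enclosing-pair scans, and the pairing
maximum comes from explicit enumeration of every nested pairing.  They are
slow and only run on tiny inputs.
"""

from __future__ import annotations

from itertools import product

PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def all_dotbracket_strings(max_len: int):
    """Every balanced dot-bracket string of length 1..max_len."""
    for n in range(1, max_len + 1):
        for chars in product("().", repeat=n):
            depth = 0
            ok = True
            for c in chars:
                if c == "(":
                    depth += 1
                elif c == ")":
                    depth -= 1
                    if depth < 0:
                        ok = False
                        break
            if ok and depth == 0:
                yield "".join(chars)


def _pairs_of(db: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            pairs.append((stack.pop(), pos))
    return sorted(pairs)


def brute_force_decomposition(db: str):
    """Per-kind position sets and counts by exhaustive per-loop scanning.

    Returns (u_p, u_n) keyed by the kind letters 'S', 'H', 'I', 'B', 'M'.
    """
    pairs = _pairs_of(db)
    pair_set = set(pairs)
    paired = {p for ij in pairs for p in ij}
    u_p = {k: set() for k in "SHIBM"}
    u_n = {k: 0 for k in "SHIBM"}

    # stems: count maximal stacked runs; every paired base is stem material
    for (i, j) in pairs:
        if (i - 1, j + 1) not in pair_set:
            u_n["S"] += 1
    u_p["S"] = paired

    # loops: for each closing pair, collect loop-interior unpaired positions
    # and directly enclosed branches by scanning every interior position and
    # testing, pair by pair, whether a smaller pair separates it from (i, j)
    for (i, j) in pairs:
        interior_unpaired = []
        branches = []
        for (k, l) in pairs:
            if i < k < l < j and not any(
                i < a < k and l < b < j for (a, b) in pairs if (a, b) != (k, l)
            ):
                branches.append((k, l))
        for p in range(i + 1, j):
            if p in paired:
                continue
            if not any(k < p < l for (k, l) in branches):
                interior_unpaired.append(p)
        if not branches:
            u_n["H"] += 1
            u_p["H"].update(interior_unpaired)
        elif len(branches) == 1:
            (k, l) = branches[0]
            if k == i + 1 and l == j - 1:
                continue  # stacked
            sides = (k - i - 1 > 0) + (j - l - 1 > 0)
            kind = "I" if sides == 2 else "B"
            u_n[kind] += 1
            u_p[kind].update(interior_unpaired)
        else:
            u_n["M"] += 1
            u_p["M"].update(interior_unpaired)
    return {k: frozenset(v) for k, v in u_p.items()}, u_n


def enumerate_max_pairs(seq: str, min_hairpin: int = 3) -> int:
    """Maximum nested pairing size by explicit enumeration (no DP tables)."""

    def best(positions: tuple[int, ...]) -> int:
        if not positions:
            return 0
        first, rest = positions[0], positions[1:]
        result = best(rest)  # first unpaired
        for idx, j in enumerate(rest):
            if j - first <= min_hairpin:
                continue
            if (seq[first - 1], seq[j - 1]) not in PAIRABLE:
                continue
            inside = tuple(p for p in rest[:idx] if first < p < j)
            outside = tuple(p for p in rest[idx + 1 :])
            result = max(result, 1 + best(inside) + best(outside))
        return result

    return best(tuple(range(1, len(seq) + 1)))
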