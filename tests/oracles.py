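"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic programming paths: the
structure enumerator is plain recursion over pairing choices, the energy
scorer decomposes loops explicitly from the pair table, and the tree
edit distance is the exponential rightmost-root recursion (memoized over
forest tuples, which is still a different algorithm than the keyroot DP
it checks).
"""

from __future__ import annotations

import functools

from presnrna.energies import DEFAULT_MODEL, PAIR_INDEX, encode
from presnrna.structio import LEGAL_PAIRS, pairs_to_dotbracket

MIN_HAIRPIN = 3


# ---------------------------------------------------------------------------
# structure enumeration
# ---------------------------------------------------------------------------

def enumerate_pair_sets(seq: str, min_hairpin: int = MIN_HAIRPIN):
    """All nested, legal-pair, min-hairpin structures of ``seq``."""

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        for s in rec(rest):
            yield s
        for j in rest:
            if j - first - 1 < min_hairpin:
                continue
            if (seq[first], seq[j]) not in LEGAL_PAIRS:
                continue
            inside = tuple(p for p in rest if first < p < j)
            outside = tuple(p for p in rest if p > j)
            for si in rec(inside):
                for so in rec(outside):
                    yield si | so | {(first, j)}

    return set(rec(tuple(range(len(seq)))))


def all_dotbrackets(n: int, min_hairpin: int = MIN_HAIRPIN) -> list[str]:
    """Every valid dot-bracket string of length ``n`` (sequence-free)."""
    seq = "G" * n  # G-G is not a legal pair; enumerate shapes directly

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        for s in rec(rest):
            yield s
        for j in rest:
            if j - first - 1 < min_hairpin:
                continue
            inside = tuple(p for p in rest if first < p < j)
            outside = tuple(p for p in rest if p > j)
            for si in rec(inside):
                for so in rec(outside):
                    yield si | so | {(first, j)}

    return sorted({pairs_to_dotbracket(sorted(s), n) for s in rec(tuple(range(n)))})


def sequence_for(dotbracket: str) -> str:
    """A sequence realizing a dot-bracket: G-C at pairs, A elsewhere."""
    seq = ["A"] * len(dotbracket)
    stack = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
            seq[i] = "G"
        elif c == ")":
            stack.pop()
            seq[i] = "C"
    return "".join(seq)


# ---------------------------------------------------------------------------
# loop-decomposition energy scorer
# ---------------------------------------------------------------------------

def score_structure(seq: str, pairs, model=DEFAULT_MODEL) -> int:
    """Energy in centikcal/mol by explicit loop decomposition."""
    enc = encode(seq)
    pt = [-1] * len(seq)
    for i, j in pairs:
        pt[i] = j
        pt[j] = i
    total = 0

    def children_of(i, j):
        out = []
        k = i + 1
        while k < j:
            if pt[k] > k:
                out.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        return out

    def walk(i, j):
        nonlocal total
        kids = children_of(i, j)
        if not kids:
            total += int(model.hairpin[j - i - 1])
        elif len(kids) == 1:
            (k, l) = kids[0]
            l1, l2 = k - i - 1, j - l - 1
            total += model.interior_energy(l1, l2, int(PAIR_INDEX[enc[i], enc[j]]),
                                           int(PAIR_INDEX[enc[k], enc[l]]))
            walk(k, l)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (model.ml_init + model.ml_branch * (len(kids) + 1)
                      + model.ml_unpaired * unpaired)
            for k, l in kids:
                walk(k, l)

    k = 0
    n = len(seq)
    while k < n:
        if pt[k] > k:
            walk(k, pt[k])
            k = pt[k] + 1
        else:
            k += 1
    return total


# ---------------------------------------------------------------------------
# brute-force tree edit distance (rightmost-root recursion)
# ---------------------------------------------------------------------------

def nested_tree(dotbracket: str):
    """('P'|'U'|'R', children tuple) nested representation."""
    pt = [-1] * len(dotbracket)
    stack = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i] = j
            pt[j] = i

    def region(i, j):
        out = []
        k = i
        while k <= j:
            if pt[k] > k:
                out.append(("P", tuple(region(k + 1, pt[k] - 1))))
                k = pt[k] + 1
            else:
                out.append(("U", ()))
                k += 1
        return out

    return ("R", tuple(region(0, len(dotbracket) - 1)))


@functools.cache
def _tree_size(t) -> int:
    return 1 + sum(_tree_size(c) for c in t[1])


@functools.cache
def _forest_dist(f1, f2) -> int:
    if not f1:
        return sum(_tree_size(t) for t in f2)
    if not f2:
        return sum(_tree_size(t) for t in f1)
    l1, r1 = f1[:-1], f1[-1]
    l2, r2 = f2[:-1], f2[-1]
    delete = _forest_dist(l1 + r1[1], f2) + 1
    insert = _forest_dist(f1, l2 + r2[1]) + 1
    match = (_forest_dist(l1, l2) + _forest_dist(r1[1], r2[1])
             + (0 if r1[0] == r2[0] else 1))
    return min(delete, insert, match)


def brute_tree_distance(db_a: str, db_b: str) -> int:
    return _forest_dist((nested_tree(db_a),), (nested_tree(db_b),))
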