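"""Ordered labeled trees from dot-brackets and tree edit distances.

A secondary structure maps to a rooted ordered tree: in the default
"full" representation every base pair becomes an internal ``P`` node,
every unpaired base a ``U`` leaf, under a virtual root; children follow
the 5'→3' order.  Distances are Zhang-Shasha ordered tree edit distances
with unit insert/delete/relabel costs, the convention of the classic
RNA structure-comparison tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import tree_edit_distance_kernel
from .structio import SecondaryStructure

#: integer node labels
LABELS = {"R": 0, "P": 1, "U": 2, "S": 3, "H": 4, "B": 5, "I": 6, "M": 7, "E": 8}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class StructureTree:
    """Postorder arrays of a rooted ordered tree.

    ``labels[k]`` is the label of postorder node ``k``; ``lml[k]`` the
    postorder index of its leftmost leaf descendant; ``keyroots`` the
    Zhang-Shasha keyroots in increasing order.  ``seq_len`` remembers the
    source sequence length for distance normalization.
    """

    labels: np.ndarray
    lml: np.ndarray
    keyroots: np.ndarray
    representation: str
    seq_len: int

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def label_names(self) -> list[str]:
        return [LABEL_NAMES[int(x)] for x in self.labels]


def _postorder_from_nested(root) -> StructureTree:
    """root = (label, [children]) nested tuples -> postorder arrays."""
    labels: list[int] = []
    lml: list[int] = []

    def walk(node):
        lab, children = node
        first_leaf = None
        for ch in children:
            idx = walk(ch)
            if first_leaf is None:
                first_leaf = lml[idx]
        labels.append(LABELS[lab])
        my = len(labels) - 1
        lml.append(first_leaf if first_leaf is not None else my)
        return my

    walk(root)
    lml_arr = np.array(lml, dtype=np.int64)
    # keyroot: highest postorder node for each distinct leftmost-leaf value
    seen = {}
    for k in range(len(lml)):
        seen[lml[k]] = k
    keyroots = np.array(sorted(seen.values()), dtype=np.int64)
    return StructureTree(
        labels=np.array(labels, dtype=np.int64),
        lml=lml_arr, keyroots=keyroots,
        representation="", seq_len=0,
    )


def _full_nested(s: SecondaryStructure):
    pt = s.pair_table

    def region(i, j):  # children for positions i..j inclusive
        children = []
        k = i
        while k <= j:
            if pt[k] > k:
                children.append(("P", region(k + 1, pt[k] - 1)))
                k = pt[k] + 1
            else:
                children.append(("U", []))
                k += 1
        return children

    return ("R", region(0, len(s) - 1))


def _coarse_nested(s: SecondaryStructure):
    """One node per structural element: stems (S), hairpin (H), bulge (B),
    internal (I) and multibranch (M) loops, under the root."""
    pt = s.pair_table

    def helix(i, j):
        # follow the stack down to the innermost pair of this stem
        while pt[i + 1] == j - 1 and i + 1 < j - 1:
            i, j = i + 1, j - 1
        children = []
        k = i + 1
        branches = []
        while k < j:
            if pt[k] > k:
                branches.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        if not branches:
            children = [("H", [])]
        elif len(branches) == 1:
            (bk, bl) = branches[0]
            loop_lab = "B" if (bk - i - 1 == 0 or j - bl - 1 == 0) else "I"
            children = [(loop_lab, [("S", helix(bk, bl))])]
        else:
            children = [("M", [("S", helix(bk, bl)) for bk, bl in branches])]
        return children

    top = []
    k = 0
    n = len(s)
    while k < n:
        if pt[k] > k:
            top.append(("S", helix(k, pt[k])))
            k = pt[k] + 1
        else:
            k += 1
    return ("R", top)


def to_tree(s: SecondaryStructure, representation: str = "full") -> StructureTree:
    """Deterministic ordered tree of a structure.

    ``full``: a ``P`` node per pair, a ``U`` leaf per unpaired base.
    ``coarse``: one node per loop-type element (S/H/B/I/M).
    """
    if representation == "full":
        nested = _full_nested(s)
    elif representation == "coarse":
        nested = _coarse_nested(s)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    t = _postorder_from_nested(nested)
    return StructureTree(labels=t.labels, lml=t.lml, keyroots=t.keyroots,
                         representation=representation, seq_len=len(s))


def tree_edit_distance(a: StructureTree, b: StructureTree) -> int:
    """Minimal edit-script cost (unit costs) between two ordered trees."""
    if a.representation != b.representation:
        raise ValueError(
            f"representation mismatch: {a.representation!r} vs {b.representation!r}"
        )
    return int(tree_edit_distance_kernel(a.lml, a.keyroots, a.labels,
                                         b.lml, b.keyroots, b.labels))


def structure_distance(a: SecondaryStructure, b: SecondaryStructure,
                       representation: str = "full") -> int:
    return tree_edit_distance(to_tree(a, representation), to_tree(b, representation))


def normalized_distance(d: float, len_a: int, len_b: int, norm: str = "mean") -> float:
    """Tree edit distance normalized to sequence length.

    ``norm`` picks the denominator: arithmetic mean (default), max or min
    of the two sequence lengths.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    if norm == "mean":
        denom = (len_a + len_b) / 2.0
    elif norm == "max":
        denom = float(max(len_a, len_b))
    elif norm == "min":
        denom = float(min(len_a, len_b))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return d / denom


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy())


class DistanceCache:
    """Memoizes tree edit distances by dot-bracket pair.

    Suboptimal ensembles of homologous variants repeat the same shapes
    many times; caching by (dot-bracket, dot-bracket) collapses the
    quadratic distance workload to the number of distinct shape pairs.
    """

    def __init__(self, representation: str = "full"):
        self.representation = representation
        self._trees: dict[str, StructureTree] = {}
        self._dist: dict[tuple[str, str], int] = {}

    def tree(self, s: SecondaryStructure) -> StructureTree:
        t = self._trees.get(s.dotbracket)
        if t is None:
            t = to_tree(s, self.representation)
            self._trees[s.dotbracket] = t
        return t

    def distance(self, a: SecondaryStructure, b: SecondaryStructure) -> int:
        key = (a.dotbracket, b.dotbracket) if a.dotbracket <= b.dotbracket \
            else (b.dotbracket, a.dotbracket)
        d = self._dist.get(key)
        if d is None:
            d = tree_edit_distance(self.tree(a), self.tree(b))
            self._dist[key] = d
        return d


def distance_matrix(structures: Sequence[SecondaryStructure],
                    labels: Optional[list[str]] = None,
                    representation: str = "full",
                    normalize: bool = False,
                    norm: str = "mean",
                    cache: Optional[DistanceCache] = None) -> DistanceMatrix:
    """Symmetric matrix of pairwise (optionally normalized) tree distances."""
    if not structures:
        raise ValueError("no structures given")
    if labels is None:
        labels = [f"s{k}" for k in range(len(structures))]
    cache = cache or DistanceCache(representation)
    n = len(structures)
    vals = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(cache.distance(structures[i], structures[j]))
            if normalize:
                d = normalized_distance(d, len(structures[i]), len(structures[j]), norm)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=labels, values=vals)
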