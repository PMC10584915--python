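"""Reduced nearest-neighbor energy model for the built-in folding engine.

The model keeps the parts of the Turner nearest-neighbor scheme that drive
helix formation and loop closure — stacking energies for the six legal
pairs, length-indexed hairpin/bulge/internal-loop initiation penalties with
Jacobson-Stockmayer log extrapolation, and an affine multiloop cost — and
drops sequence-dependent loop terminal corrections, dangles and special
loops.  It is deliberately small so that exhaustive enumeration oracles can
verify the dynamic programming engine exactly, while remaining faithful
enough that GC-rich helices are strongly stable and A-U/G-U helices (the
hallmark of the U-rich region around the Sm site) are only marginally
stable.

All energies are handled internally as integer hundredths of kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Base encoding used by the numeric kernels.
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

#: Pair-type encoding; -1 marks an illegal pair.
#: Order: AU=0, CG=1, GC=2, GU=3, UA=4, UG=5.
PAIR_INDEX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([("A", "U"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "A"), ("U", "G")]):
    PAIR_INDEX[BASE_INDEX[_a], BASE_INDEX[_b]] = _k

PAIR_NAMES = ["AU", "CG", "GC", "GU", "UA", "UG"]

#: Stacking free energies (kcal/mol) for outer pair (5'i-j3') on inner pair
#: (i+1, j-1).  Watson-Crick-on-Watson-Crick entries follow Turner-style
#: magnitudes; wobble-on-wobble stacks are kept weakly stabilizing.
_STACK = {
    ("AU", "AU"): -0.9, ("AU", "CG"): -2.2, ("AU", "GC"): -2.1,
    ("AU", "GU"): -0.6, ("AU", "UA"): -1.1, ("AU", "UG"): -1.4,
    ("CG", "AU"): -2.1, ("CG", "CG"): -3.3, ("CG", "GC"): -2.4,
    ("CG", "GU"): -1.4, ("CG", "UA"): -2.1, ("CG", "UG"): -2.1,
    ("GC", "AU"): -2.4, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3,
    ("GC", "GU"): -1.5, ("GC", "UA"): -2.2, ("GC", "UG"): -2.5,
    ("GU", "AU"): -1.3, ("GU", "CG"): -2.5, ("GU", "GC"): -2.1,
    ("GU", "GU"): -0.5, ("GU", "UA"): -1.4, ("GU", "UG"): -0.4,
    ("UA", "AU"): -1.3, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1,
    ("UA", "GU"): -1.0, ("UA", "UA"): -0.9, ("UA", "UG"): -1.3,
    ("UG", "AU"): -1.0, ("UG", "CG"): -1.5, ("UG", "GC"): -1.4,
    ("UG", "GU"): -0.2, ("UG", "UA"): -0.6, ("UG", "UG"): -0.5,
}

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 1.8, 3: 2.0, 4: 2.2, 5: 2.4, 6: 3.0}

#: Jacobson-Stockmayer coefficient for loop-size extrapolation (kcal/mol).
_LXC = 1.08

MAXLOOP = 30  # largest unpaired span considered inside an interior loop


def _table(base: dict[int, float], max_size: int) -> np.ndarray:
    """Length-indexed penalty table with log extrapolation past the data."""
    out = np.zeros(max_size + 1, dtype=np.int64)
    ref = max(base)
    for size in range(1, max_size + 1):
        if size in base:
            val = base[size]
        elif size < min(base):
            val = float("inf")
        else:
            val = base[ref] + _LXC * math.log(size / ref)
        out[size] = int(round(val * 100)) if math.isfinite(val) else 10**7
    return out


@dataclass
class EnergyModel:
    """Parameter container for the reduced nearest-neighbor model.

    ``stack[p, q]`` is the stacking term (centikcal/mol) for inner pair
    type ``q`` stacked on outer pair type ``p``; loop tables are indexed by
    unpaired length.  Multiloop cost is ``ml_init + ml_branch * branches +
    ml_unpaired * unpaired``.
    """

    min_hairpin: int = 3
    maxloop: int = MAXLOOP
    ml_init: int = 340      # multiloop closing penalty
    ml_branch: int = 40     # per branch (incl. closing pair)
    ml_unpaired: int = 0    # per unpaired multiloop nucleotide
    stack: np.ndarray = field(default_factory=lambda: _stack_array())
    hairpin: np.ndarray = field(default_factory=lambda: _table(_HAIRPIN, 300))
    bulge: np.ndarray = field(default_factory=lambda: _table(_BULGE, 300))
    internal: np.ndarray = field(default_factory=lambda: _table(_INTERNAL, 300))

    def stack_energy(self, outer: str, inner: str) -> float:
        """Stacking term in kcal/mol for named pairs, e.g. ('GC', 'AU')."""
        return self.stack[PAIR_NAMES.index(outer), PAIR_NAMES.index(inner)] / 100.0

    def interior_energy(self, l1: int, l2: int, outer_pt: int, inner_pt: int) -> int:
        """Energy (centikcal) of the interior loop with ``l1``/``l2``
        unpaired nucleotides on the 5'/3' side; 0/0 is a stack."""
        if l1 == 0 and l2 == 0:
            return int(self.stack[outer_pt, inner_pt])
        if l1 == 0 or l2 == 0:
            return int(self.bulge[l1 + l2])
        return int(self.internal[l1 + l2])


def _stack_array() -> np.ndarray:
    arr = np.zeros((6, 6), dtype=np.int64)
    for (a, b), v in _STACK.items():
        arr[PAIR_NAMES.index(a), PAIR_NAMES.index(b)] = int(round(v * 100))
    return arr


DEFAULT_MODEL = EnergyModel()


def encode(seq: str) -> np.ndarray:
    return np.array([BASE_INDEX[c] for c in seq], dtype=np.int8)
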