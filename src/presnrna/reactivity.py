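"""SHAPE reactivity profiles: folding constraints and differential windows.

2'-OH acylation reactivities report per-nucleotide backbone flexibility:
highly reactive positions are almost certainly single-stranded, so they
convert to 'x' hard constraints for structure prediction.  Comparing two
conditions (e.g. deproteinized versus in-cell RNA) uses the windowed
differential-reactivity convention: 3-nt smoothed differences, a Z-factor
gate against measurement error, a standard-score gate against the
transcript-wide difference distribution, and a 3-of-5 window call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .structio import ConstraintSpec, normalize_rna

DEFAULT_UNPAIRED_THRESHOLD = 0.4
SMOOTHING_WINDOW = 3


@dataclass
class ReactivityProfile:
    """Per-nucleotide SHAPE reactivities with standard errors.

    Missing measurements are NaN and propagate through all derived
    quantities.
    """

    sequence: str
    reactivity: np.ndarray
    stderr: Optional[np.ndarray] = None

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if len(self.stderr) != len(self.sequence):
                raise ValueError("stderr length differs from sequence length")
        if len(self.reactivity) != len(self.sequence):
            raise ValueError("reactivity length differs from sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_tsv(cls, path) -> "ReactivityProfile":
        """Columns: position (1-based), sequence, reactivity, stderr;
        missing values as 'nan' or empty."""
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        seq = "".join(df[cols["sequence"]].astype(str))
        err = df[cols["stderr"]].to_numpy(float) if "stderr" in cols else None
        return cls(sequence=seq, reactivity=df[cols["reactivity"]].to_numpy(float),
                   stderr=err)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "position": np.arange(1, len(self) + 1),
            "sequence": list(self.sequence),
            "reactivity": self.reactivity,
        })
        if self.stderr is not None:
            df["stderr"] = self.stderr
        df.to_csv(path, sep="\t", index=False)


def reactivity_to_constraints(p: ReactivityProfile,
                              unpaired_threshold: float = DEFAULT_UNPAIRED_THRESHOLD,
                              ) -> ConstraintSpec:
    """'x' at positions with reactivity >= threshold; '.' elsewhere.

    Missing reactivities stay unconstrained.  Raising the threshold never
    adds a constraint.
    """
    if np.all(np.isnan(p.reactivity)):
        warnings.warn("all reactivities missing: returning free constraint", stacklevel=2)
    with np.errstate(invalid="ignore"):
        mask = p.reactivity >= unpaired_threshold
    mask &= ~np.isnan(p.reactivity)
    return ConstraintSpec("".join("x" if m else "." for m in mask))


def _smooth(values: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving mean ignoring NaN; NaN where the window is empty."""
    n = len(values)
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        seg = values[max(0, i - half): min(n, i + half + 1)]
        good = seg[~np.isnan(seg)]
        if good.size:
            out[i] = good.mean()
    return out


@dataclass
class DeltaWindowResult:
    standard_score: np.ndarray
    z_factor: np.ndarray
    significant_regions: list[tuple[int, int]] = field(default_factory=list)
    passing: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def delta_windows(a: ReactivityProfile, b: ReactivityProfile,
                  window: int = 5, min_hits: int = 3) -> DeltaWindowResult:
    """Windowed differential-reactivity significance calls.

    Per nucleotide, the smoothed difference d = smooth(a) - smooth(b) is
    scored two ways: the Z-factor ``1 - 1.96 (sa + sb) / |d|`` (positive
    when the difference clears the propagated smoothed errors) and the
    standard score of d against the transcript-wide difference
    distribution.  A nucleotide passes when Z-factor > 0 and
    |standard score| >= 1; positions lying in any ``window``-wide stretch
    with >= ``min_hits`` passing nucleotides and passing themselves form
    the significant regions (0-based half-open).  Region calls are
    symmetric in the two profiles.
    """
    if len(a) != len(b):
        raise ValueError("profiles have different lengths")
    if a.stderr is None or b.stderr is None:
        raise ValueError("both profiles need standard errors for the Z-factor")
    n = len(a)
    diff = _smooth(a.reactivity) - _smooth(b.reactivity)
    sa = _smooth(a.stderr)
    sb = _smooth(b.stderr)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_factor = 1.0 - 1.96 * (sa + sb) / np.abs(diff)
    good = ~np.isnan(diff)
    mu = diff[good].mean() if good.any() else np.nan
    sd = diff[good].std(ddof=0) if good.any() else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        standard_score = (diff - mu) / sd if sd and sd > 0 else np.zeros(n) * np.nan
    passing = np.zeros(n, dtype=bool)
    ok = good & ~np.isnan(z_factor)
    passing[ok] = (z_factor[ok] > 0) & (np.abs(standard_score[ok]) >= 1)

    in_region = np.zeros(n, dtype=bool)
    for start in range(0, max(1, n - window + 1)):
        w = passing[start:start + window]
        if w.sum() >= min_hits:
            seg = np.arange(start, min(n, start + window))
            in_region[seg[passing[seg]]] = True

    regions = []
    i = 0
    while i < n:
        if in_region[i]:
            j = i
            while j + 1 < n and in_region[j + 1]:
                j += 1
            regions.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return DeltaWindowResult(standard_score=standard_score, z_factor=z_factor,
                             significant_regions=regions, passing=passing)
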