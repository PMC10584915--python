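"""Conservation statistics: clade similarity tables, t-tests, box plots.

Structural conservation of a pre-snRNA within a clade is summarized as
the mean pairwise normalized tree edit distance among the chosen
representative structures — smaller means more similar.  Clades are
compared with the pooled-variance (equal-variance) two-sample two-tailed
t-test; quartiles follow the midpoint-interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .treedist import DistanceMatrix


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float

    def as_dict(self) -> dict:
        return {"t": self.t_statistic, "df": self.degrees_of_freedom, "p": self.p_value}


def mean_pairwise_similarity(dm: DistanceMatrix) -> float:
    """Mean of the upper-triangle distances of a (normalized) matrix."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    iu = np.triu_indices(n, k=1)
    return float(np.mean(dm.values[iu]))


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample two-tailed t-test.

    df = len(a) + len(b) - 2.  Degenerate zero-variance inputs: equal
    means give t = 0, p = 1; unequal means are an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    df = len(a) + len(b) - 2
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(t_statistic=0.0, degrees_of_freedom=df, p_value=1.0)
        raise ValueError("zero pooled variance with unequal means")
    t, p = sp_stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t_statistic=float(t), degrees_of_freedom=df, p_value=float(p))


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Quartiles (midpoint interpolation), 1.5×IQR fences, whiskers at the
    most extreme non-outlier points."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    q1, med, q3 = (float(np.quantile(v, q, method="midpoint")) for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    # degenerate spread: nothing inside the fences -> whiskers collapse
    # onto the quartiles
    w_lo = float(inside[0]) if inside.size else q1
    w_hi = float(inside[-1]) if inside.size else q3
    return BoxplotSummary(
        median=med, q1=q1, q3=q3,
        whisker_low=w_lo, whisker_high=w_hi,
        outliers=[float(x) for x in outliers],
    )


# ---------------------------------------------------------------------------
# Similarity tables
# ---------------------------------------------------------------------------

class SimilarityTable:
    """Per-RNA per-clade mean normalized distances (lower = more similar)."""

    def __init__(self, frame: pd.DataFrame):
        if (frame.to_numpy(dtype=float) < 0).any():
            raise ValueError("similarity-table distances must be >= 0")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "SimilarityTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].dropna().to_numpy(dtype=float)

    def compare(self, col_a: str, col_b: str) -> TTestResult:
        return two_sample_ttest(self.column(col_a), self.column(col_b))


def load_reference_similarities() -> SimilarityTable:
    """The packaged per-clade mean-distance table for the major and minor
    spliceosomal pre-snRNAs (the published per-clade averages)."""
    path = resources.files("presnrna").joinpath("data/clade_similarities.tsv")
    with path.open() as fh:
        return SimilarityTable(pd.read_csv(fh, sep="\t", index_col=0))
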