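"""ChIP cluster occupancy comparison downstream of peak calling.

Two questions about a pair of cluster (peak) sets from the same factor under
two treatments: (i) is one set of binding sites contained within the other,
and (ii) does one treatment put systematically more reads on the shared
clusters.  The first is an interval containment fraction; the second is the
per-cluster log2 read-count ratio distribution with a one-sample test of
mean zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ClusterSet", "LogRatioResult", "containment_fraction",
           "log_ratio_analysis"]

#: Histogram bin width for reporting log2 ratios, in log2 units.
HIST_BIN_WIDTH = 0.25


@dataclass
class ClusterSet:
    """Genomic intervals (0-based half-open) with per-interval read counts.

    ``frame`` has columns chrom, start, end, name, count; intervals are
    sorted by (chrom, start) and non-overlapping within the set.
    """

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "name", "count"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"missing columns: {sorted(req - set(self.frame.columns))}")
        f = self.frame.sort_values(["chrom", "start"], kind="stable")
        f = f.reset_index(drop=True)
        if (f["start"] >= f["end"]).any():
            raise ValueError("intervals must have start < end")
        if (f["count"] < 0).any():
            raise ValueError("read counts must be >= 0")
        same = f["chrom"].eq(f["chrom"].shift())
        if (same & (f["start"] < f["end"].shift())).any():
            raise ValueError("intervals overlap within the set")
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)


def containment_fraction(a: ClusterSet, b: ClusterSet,
                         min_overlap_bp: int = 1) -> float:
    """Fraction of intervals in ``a`` overlapping an interval of ``b`` by at
    least ``min_overlap_bp`` bases (linear sweep over the sorted sets)."""
    if len(a) == 0:
        raise ValueError("containment fraction undefined for empty query set")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    hits = 0
    b_by_chrom = {c: g for c, g in b.frame.groupby("chrom")}
    for chrom, grp in a.frame.groupby("chrom"):
        if chrom not in b_by_chrom:
            continue
        bs = b_by_chrom[chrom]["start"].to_numpy()
        be = b_by_chrom[chrom]["end"].to_numpy()
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            if hi > lo:
                overlap = np.minimum(e, be[lo:hi]) - np.maximum(s, bs[lo:hi])
                if (overlap >= min_overlap_bp).any():
                    hits += 1
    return hits / len(a)


@dataclass
class LogRatioResult:
    """Per-cluster log2 count ratios with a mean-zero t-test and histogram."""

    ratios: np.ndarray
    mean: float
    p_mean_zero: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    @property
    def se(self) -> float:
        return float(self.ratios.std(ddof=1) / np.sqrt(self.ratios.size))


def log_ratio_analysis(paired_counts: list[tuple[float, float]] | np.ndarray,
                       pseudocount: float = 0.5) -> LogRatioResult:
    """log2((ref + pc)/(test + pc)) per cluster, one-sample t-test of mean 0.

    A mean above zero means the reference condition puts more reads on the
    clusters.  The histogram uses 0.25-log2-unit bins aligned to zero.
    """
    pairs = np.asarray(paired_counts, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (ref, test) count pairs")
    ratios = np.log2((pairs[:, 0] + pseudocount) / (pairs[:, 1] + pseudocount))
    mean = float(ratios.mean())
    if np.allclose(ratios.std(ddof=1), 0.0):
        p = 1.0 if np.isclose(mean, 0.0) else 0.0
    else:
        p = float(stats.ttest_1samp(ratios, 0.0).pvalue)
    lo = np.floor(ratios.min() / HIST_BIN_WIDTH) * HIST_BIN_WIDTH
    hi = np.ceil(ratios.max() / HIST_BIN_WIDTH) * HIST_BIN_WIDTH
    edges = np.arange(lo, hi + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH)
    if edges.size < 2:
        edges = np.array([lo - HIST_BIN_WIDTH / 2, lo + HIST_BIN_WIDTH / 2])
    counts, edges = np.histogram(ratios, bins=edges)
    return LogRatioResult(ratios, mean, p, edges, counts)
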