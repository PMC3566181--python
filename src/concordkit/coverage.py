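"""Depth-of-coverage profiling: mean coverage, depth histograms with a
Poisson reference model, GC-vs-coverage windows, and PCR-duplicate marking.

The Poisson model serves two purposes: overlaying an idealised coverage
distribution on the observed depth histogram, and deriving depth thresholds
(two-tailed) used to filter variant calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval

__all__ = [
    "DepthHistogram",
    "GcWindow",
    "compute_mean_coverage",
    "depth_histogram",
    "poisson_expected",
    "poisson_depth_bounds",
    "gc_coverage_windows",
    "mark_duplicates",
]


@dataclass(frozen=True)
class DepthHistogram:
    """Fraction of reference bases at each depth, depth-0 bases included."""

    fractions: Mapping[int, float]
    total_bases: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be >= 0")


@dataclass(frozen=True)
class GcWindow:
    """One non-overlapping genomic window with its GC fraction and mean depth.

    ``gc_fraction`` is computed over non-N bases only; ``partial`` marks the
    trailing window of a chromosome when it is shorter than the configured
    width.
    """

    interval: Interval
    gc_fraction: float
    mean_depth: float
    partial: bool = False


def compute_mean_coverage(aligned_bases: int, genome_non_n_bases: int) -> float:
    """Mean coverage C = aligned bases / non-N reference bases."""
    if genome_non_n_bases <= 0:
        raise ValueError("genome_non_n_bases must be > 0")
    if aligned_bases < 0:
        raise ValueError("aligned_bases must be >= 0")
    return aligned_bases / genome_non_n_bases


def depth_histogram(per_base_depths: Sequence[int] | np.ndarray) -> DepthHistogram:
    """Histogram of per-base depths as fractions of all bases (zeros included)."""
    depths = np.asarray(per_base_depths)
    if depths.size == 0:
        raise ValueError("empty depth sequence")
    if depths.min() < 0:
        raise ValueError("depths must be >= 0")
    values, counts = np.unique(depths, return_counts=True)
    n = depths.size
    fractions = {int(v): float(c) / n for v, c in zip(values, counts)}
    return DepthHistogram(fractions=fractions, total_bases=int(n))


def poisson_expected(lam: float, max_depth: int) -> dict[int, float]:
    """Poisson pmf table e^{-lam} lam^d / d! for d = 0..max_depth.

    Computed in log space (via the scipy implementation) so rates up to ~1e4
    remain numerically stable.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    d = np.arange(max_depth + 1)
    pmf = stats.poisson.pmf(d, lam)
    return {int(k): float(p) for k, p in zip(d, pmf)}


def poisson_depth_bounds(lam: float, alpha: float) -> tuple[int, int]:
    """Two-tailed depth thresholds under a Poisson(lam) coverage model.

    Returns ``(min_depth, max_depth)`` where ``max_depth`` is the smallest d
    with CDF(d) >= 1 - alpha and ``min_depth`` is the largest d with
    CDF(d - 1) <= alpha (0 if no positive d qualifies).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    max_depth = int(stats.poisson.ppf(1 - alpha, lam))
    # ppf returns the smallest d with CDF(d) >= q already; guard round-off.
    while stats.poisson.cdf(max_depth, lam) < 1 - alpha:
        max_depth += 1
    while max_depth > 0 and stats.poisson.cdf(max_depth - 1, lam) >= 1 - alpha:
        max_depth -= 1
    min_depth = 0
    d = 1
    while stats.poisson.cdf(d - 1, lam) <= alpha:
        min_depth = d
        d += 1
    return min_depth, max_depth


def gc_coverage_windows(
    reference: Mapping[str, str],
    per_base_depths: Mapping[str, Sequence[int] | np.ndarray],
    window_bp: int,
) -> list[GcWindow]:
    """Tile each chromosome into non-overlapping windows and report the GC
    fraction and mean depth of each.

    N bases are excluded from the GC numerator and denominator; windows made
    entirely of Ns are omitted. Mean depth is over the full window length, so
    summing length x mean_depth over windows recovers the chromosome's total
    aligned base count.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    out: list[GcWindow] = []
    for chrom, seq in reference.items():
        depths = np.asarray(per_base_depths[chrom], dtype=float)
        if depths.size != len(seq):
            raise ValueError(
                f"{chrom}: depth track length {depths.size} != sequence length {len(seq)}"
            )
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        is_gc = (arr == b"G") | (arr == b"C")
        is_n = ~((arr == b"A") | (arr == b"T") | is_gc)
        for start in range(0, len(seq), window_bp):
            end = min(start + window_bp, len(seq))
            non_n = int((~is_n[start:end]).sum())
            if non_n == 0:
                continue
            gc = float(is_gc[start:end].sum()) / non_n
            out.append(GcWindow(
                interval=Interval(chrom, start, end),
                gc_fraction=gc,
                mean_depth=float(depths[start:end].mean()),
                partial=(end - start) < window_bp,
            ))
    return out


def fit_gc_bias(windows: Sequence[GcWindow]) -> tuple[float, float, float]:
    """Least-squares fit of log(mean depth) against (GC - 0.5) over windows.

    Returns ``(intercept, slope, slope_se)`` for the log-linear coverage
    model ``log depth = intercept + slope * (gc - 0.5)``. Windows with zero
    mean depth are excluded (their log is undefined).
    """
    pts = [(w.gc_fraction - 0.5, np.log(w.mean_depth))
           for w in windows if w.mean_depth > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 windows with positive depth")
    x, y = map(np.asarray, zip(*pts))
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.stderr)


def mark_duplicates(records: pd.DataFrame) -> tuple[pd.Series, int]:
    """Flag putative PCR duplicates by identical alignment coordinates.

    ``records`` columns: chrom, start, strand and (optionally) mate_chrom,
    mate_start for paired data. Within each group sharing all coordinate
    fields, every record after the first-seen one is flagged; the flagged
    count is ``group size - 1`` summed over groups.
    """
    required = ["chrom", "start", "strand"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    keys = list(required)
    for c in ("mate_chrom", "mate_start"):
        if c in records.columns:
            keys.append(c)
    flags = records.duplicated(subset=keys, keep="first")
    return flags, int(flags.sum())
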