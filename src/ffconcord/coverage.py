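"""Coverage QC statistics: threshold fractions, windowed uniformity, dropout.

Three read-depth summaries that separate a well-behaved library from a
degraded one:

* the base-weighted fraction of the genome at or above each depth threshold
  (did the sample reach its target depth?),
* the standard deviation of mean depth in fixed genomic windows (100 kb by
  default) - higher values denote poorer coverage uniformity,
* AT/GC dropout: the percentage of depth mass missing from AT-rich (GC < 50%)
  or GC-rich (GC > 50%) windows relative to their genomic abundance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageBin

__all__ = [
    "CoverageSummary",
    "depth_threshold_fractions",
    "coverage_uniformity_sd",
    "gc_dropout_scores",
    "summarize_coverage",
]

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_THRESHOLDS = (10, 30, 50, 70)


@dataclass
class CoverageSummary:
    mean_depth: float
    fraction_at_threshold: dict[float, float]
    window_sd: float
    at_dropout: float | None = None
    gc_dropout: float | None = None


def depth_threshold_fractions(
    bins: Sequence[CoverageBin],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[float, float]:
    """Fraction of binned bases lying in bins with depth >= each threshold.

    Fractions are base-weighted, so unequal bin widths count by their span.
    Monotone non-increasing in the threshold by construction.
    """
    if not bins:
        raise ValueError("cannot compute threshold fractions on empty bins")
    widths = np.array([b.width for b in bins], dtype=float)
    depths = np.array([b.depth for b in bins])
    total = widths.sum()
    return {float(t): float(widths[depths >= t].sum() / total)
            for t in thresholds}


def coverage_uniformity_sd(
    bins: Sequence[CoverageBin],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Aggregate bins into fixed windows and report the SD of window depths.

    Bins are assigned to ``window_size`` windows by overlap; each window's
    depth is the base-weighted mean of its overlapping bins (windows
    truncated at chromosome ends keep base weighting). Returns the
    per-window table and a summary with the genome-wide population SD plus
    one ``sd_<chrom>`` entry per chromosome. Higher SD means poorer
    uniformity.
    """
    if not bins:
        raise ValueError("cannot compute uniformity on empty bins")
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    depth_sum: dict[tuple[str, int], float] = defaultdict(float)
    base_sum: dict[tuple[str, int], float] = defaultdict(float)
    for b in bins:
        w = b.start // window_size
        while w * window_size < b.end:
            ov = min(b.end, (w + 1) * window_size) - max(b.start, w * window_size)
            key = (b.chrom, w)
            depth_sum[key] += b.depth * ov
            base_sum[key] += ov
            w += 1
    rows = [
        {"chrom": chrom, "start": w * window_size, "end": (w + 1) * window_size,
         "depth": depth_sum[(chrom, w)] / base_sum[(chrom, w)]}
        for (chrom, w) in sorted(depth_sum)
    ]
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
    summary = {"sd": float(np.std(windows["depth"]))}
    for chrom, grp in windows.groupby("chrom"):
        summary[f"sd_{chrom}"] = float(np.std(grp["depth"]))
    return windows, summary


def gc_dropout_scores(bins: Sequence[CoverageBin]) -> tuple[float, float]:
    """Picard-style AT and GC dropout on percentage scale.

    Bins are grouped by integer GC percentage. With ``w`` the fraction of
    bins in a class and ``r`` the fraction of total depth mass it holds,
    AT dropout sums ``max(0, w - r) * 100`` over classes below 50% GC and GC
    dropout over classes above 50%. Both are 0 for perfectly GC-neutral
    coverage and invariant to uniform depth rescaling.
    """
    if not bins:
        raise ValueError("cannot compute dropout on empty bins")
    missing = [b for b in bins if b.gc is None]
    if missing:
        raise ValueError(
            f"{len(missing)} bins lack a GC fraction (first: "
            f"{missing[0].chrom}:{missing[0].start})")
    gc_class = np.array([int(round(b.gc * 100)) for b in bins])
    depths = np.array([b.depth for b in bins], dtype=float)
    total_depth = depths.sum()
    n = len(bins)
    at = gc = 0.0
    for cls in np.unique(gc_class):
        mask = gc_class == cls
        w = mask.sum() / n
        r = depths[mask].sum() / total_depth if total_depth > 0 else 0.0
        if cls < 50:
            at += max(0.0, w - r)
        elif cls > 50:
            gc += max(0.0, w - r)
    return 100.0 * at, 100.0 * gc


def summarize_coverage(
    bins: Sequence[CoverageBin],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> CoverageSummary:
    """One-stop summary; dropout scores are included when all bins carry GC."""
    widths = np.array([b.width for b in bins], dtype=float)
    depths = np.array([b.depth for b in bins])
    mean_depth = float((depths * widths).sum() / widths.sum())
    _, sd_summary = coverage_uniformity_sd(bins, window_size)
    at_drop = gc_drop = None
    if all(b.gc is not None for b in bins):
        at_drop, gc_drop = gc_dropout_scores(bins)
    return CoverageSummary(
        mean_depth=mean_depth,
        fraction_at_threshold=depth_threshold_fractions(bins, thresholds),
        window_sd=sd_summary["sd"],
        at_dropout=at_drop,
        gc_dropout=gc_drop,
    )
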