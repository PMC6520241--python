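"""Copy-number Log2 ratio profiles and FF-vs-FFPE rank-correlation concordance.

The Log2 ratio (Log2R) of a genomic bin is log2 of the library-size
normalized tumor/normal depth ratio: 0 for copy-neutral, +1 for a doubled
segment, -1 for a single-copy loss in a pure diploid tumor. Concordance
between specimens is measured as the Spearman rank correlation of per-bin
Log2R over bins usable in both profiles, the bin-level analogue of comparing
two noisy copy-number landscapes without segmenting either.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CoverageBin

__all__ = [
    "CnaProfile",
    "compute_log2r",
    "log2r_correlation",
    "compare_conditions",
]

MIN_COMMON_BINS = 30


@dataclass
class CnaProfile:
    """Per-bin Log2R (and optional BAF) for one tumor/normal pair.

    ``bins`` columns: chrom, start, end, log2r, optionally baf. Masked bins
    (e.g. insufficient normal depth) carry NaN log2r and are excluded from
    correlations.
    """

    bins: pd.DataFrame
    sample_label: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "log2r"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"CnaProfile bins missing columns: {sorted(missing)}")
        self.bins = self.bins.sort_values(
            ["chrom", "start"], kind="mergesort", ignore_index=True)

    @property
    def n_usable(self) -> int:
        return int(self.bins["log2r"].notna().sum())

    def to_bedgraph(self, path: str | Path) -> None:
        usable = self.bins[self.bins["log2r"].notna()]
        with open(path, "w") as fh:
            for row in usable.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.log2r:g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, sample_label: str = "") -> "CnaProfile":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             float(parts[3])))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "log2r"])
        return cls(bins=df, sample_label=sample_label or Path(path).stem)


def compute_log2r(tumor_bins: Sequence[CoverageBin],
                  normal_bins: Sequence[CoverageBin],
                  min_normal_depth: float = 10.0,
                  sample_label: str = "") -> CnaProfile:
    """Per-bin log2 of the library-size-normalized tumor/normal depth ratio.

    ``log2r_i = log2((t_i / T) / (n_i / N))`` with T, N the total depth of
    each track, making the result invariant to rescaling either library.
    Tumor and normal tracks must share an identical bin grid; bins whose
    normal depth falls below ``min_normal_depth`` (or with zero depth in
    either track) are masked as NaN rather than dropped.
    """
    t_keys = [(b.chrom, b.start, b.end) for b in tumor_bins]
    n_keys = [(b.chrom, b.start, b.end) for b in normal_bins]
    if sorted(t_keys) != sorted(n_keys):
        raise ValueError("tumor and normal coverage tracks have mismatched bin "
                         "grids; re-bin to common boundaries first")
    t_order = sorted(range(len(tumor_bins)), key=lambda i: t_keys[i])
    n_order = sorted(range(len(normal_bins)), key=lambda i: n_keys[i])
    t = np.array([tumor_bins[i].depth for i in t_order])
    n = np.array([normal_bins[i].depth for i in n_order])
    T, N = t.sum(), n.sum()
    if T <= 0 or N <= 0:
        raise ValueError("a coverage track with zero total depth has no Log2R")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2((t / T) / (n / N))
    log2r[(n < min_normal_depth) | (t <= 0) | (n <= 0)] = np.nan
    keys = [t_keys[i] for i in t_order]
    df = pd.DataFrame({
        "chrom": [k[0] for k in keys],
        "start": [k[1] for k in keys],
        "end": [k[2] for k in keys],
        "log2r": log2r,
    })
    return CnaProfile(bins=df, sample_label=sample_label)


def _common_log2r(a: CnaProfile, b: CnaProfile) -> pd.DataFrame:
    merged = a.bins.merge(b.bins, on=["chrom", "start", "end"],
                          suffixes=("_a", "_b"))
    return merged.dropna(subset=["log2r_a", "log2r_b"])


def log2r_correlation(a: CnaProfile, b: CnaProfile) -> float:
    """Spearman rank correlation of per-bin Log2R over shared usable bins.

    Bins masked in either profile are excluded; ties receive mid-ranks.
    Raises when fewer than 30 bins remain (the estimate is too unstable to
    report).
    """
    common = _common_log2r(a, b)
    if len(common) < MIN_COMMON_BINS:
        raise ValueError(
            f"only {len(common)} common usable bins between "
            f"{a.sample_label!r} and {b.sample_label!r}; "
            f"need >= {MIN_COMMON_BINS}")
    rho, _ = stats.spearmanr(common["log2r_a"], common["log2r_b"])
    return float(rho)


def compare_conditions(profiles: Sequence[tuple[str, CnaProfile]],
                       reference: CnaProfile) -> pd.DataFrame:
    """Rank experimental conditions by Log2R concordance with a reference.

    Returns a DataFrame (label, spearman, n_bins) sorted by descending
    correlation - the shape used to compare DNA-extraction protocols against
    the matched fresh-frozen profile.
    """
    rows = []
    for label, profile in profiles:
        common = _common_log2r(reference, profile)
        rho = log2r_correlation(reference, profile)
        rows.append({"label": label, "spearman": rho, "n_bins": len(common)})
    df = pd.DataFrame(rows, columns=["label", "spearman", "n_bins"])
    return df.sort_values("spearman", ascending=False, ignore_index=True)
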