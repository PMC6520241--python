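"""Readers, writers and the canonical variant representation.

Somatic call sets arrive as VCF (1-based), region strata as BED and coverage
tracks as bedGraph (both 0-based half-open). Everything downstream works on
the types defined here; coordinate conventions are converted only at these
I/O boundaries.

Variant identity throughout the package is the exact ``(chrom, pos, ref, alt)``
tuple *after* :func:`normalize_variant`, so call sets produced by different
callers become comparable.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "VariantRecord",
    "GenomicRegionSet",
    "CoverageBin",
    "normalize_chrom",
    "normalize_variant",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "attach_gc",
]

_VALID_CLASSES = ("SNV", "INS", "DEL", "MNV")


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return "MNV"


@dataclass(frozen=True)
class VariantRecord:
    """One somatic small variant with its read-count evidence.

    ``pos`` is 1-based (VCF convention). ``depth`` and ``alt_count`` may be
    ``None`` when the source VCF carried no usable DP/AD evidence; such
    records are kept, flagged by the missing depth, never silently dropped.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None
    alt_count: int | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if self.depth is not None:
            if self.depth < 0:
                raise ValueError("depth must be >= 0")
            if self.alt_count is not None and self.alt_count > self.depth:
                raise ValueError(
                    f"alt_count {self.alt_count} exceeds depth {self.depth} "
                    f"at {self.chrom}:{self.pos}"
                )
        if self.alt_count is not None and self.alt_count < 0:
            raise ValueError("alt_count must be >= 0")

    @property
    def vclass(self) -> str:
        return _variant_class(self.ref, self.alt)

    @property
    def af(self) -> float | None:
        """Allelic fraction alt_count/depth; None when depth is 0 or unknown."""
        if self.depth is None or self.alt_count is None or self.depth == 0:
            return None
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_chrom(name: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Harmonize chromosome-name dialects; default strips a leading ``chr``."""
    if alias_map is not None and name in alias_map:
        return alias_map[name]
    if name.startswith("chr"):
        return name[3:]
    return name


def normalize_variant(v: VariantRecord) -> VariantRecord:
    """Left-align and minimalize an allele pair (shared suffix, then prefix).

    Uses allele strings only (no reference FASTA). Idempotent; SNVs pass
    through unchanged. Raises on ``ref == alt``.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    if ref == alt:
        raise ValueError(f"not a variant: ref == alt ({ref}) at {v.chrom}:{v.pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return replace(v, ref=ref, alt=alt, pos=pos)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _pick_sample(samples: Sequence[str], sample_role: str) -> int:
    """Choose the sample column for a role.

    Matches TUMOR/NORMAL by name (case-insensitive) when present; otherwise a
    single sample serves either role and for paired VCFs the somatic-caller
    convention normal-first/tumor-second is assumed.
    """
    lowered = [s.lower() for s in samples]
    target = sample_role.lower()
    for i, s in enumerate(lowered):
        if target in s:
            return i
    if len(samples) == 1:
        return 0
    return 1 if sample_role == "tumor" else 0


def read_vcf(
    path: str | Path,
    sample_role: str = "tumor",
    harmonize: bool = True,
    alias_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read somatic calls from a VCF 4.x file into normalized records.

    One record per (site, ALT allele); multi-allelic lines are split. Depth
    and alt-count come from FORMAT AD/DP of the requested sample (``tumor``
    or ``normal``), falling back to INFO DP; records without evidence keep
    ``depth=None``. Output sorted by (chrom, pos, ref, alt).
    """
    if sample_role not in ("tumor", "normal"):
        raise ValueError(f"sample_role must be 'tumor' or 'normal', got {sample_role!r}")
    path = Path(path)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        sample_idx = _pick_sample(samples, sample_role) if samples else None
        # body line numbers for error messages: header lines + 1-based record index
        n_header = sum(1 for line in str(vf.header).splitlines() if line.strip())
        i = 0
        try:
            for i, rec in enumerate(vf, start=1):
                records.extend(
                    _records_from_vcf_line(rec, samples, sample_idx, harmonize, alias_map)
                )
        except Exception as exc:  # pragma: no cover - depends on pysam error paths
            raise ValueError(
                f"malformed VCF record at {path} line ~{n_header + i + 1}: {exc}"
            ) from exc
    records.sort(key=lambda v: v.key)
    return records


def _records_from_vcf_line(rec, samples, sample_idx, harmonize, alias_map):
    chrom = normalize_chrom(rec.chrom, alias_map) if harmonize else rec.chrom
    alts = rec.alts or ()
    depth: int | None = None
    ad: Sequence[int] | None = None
    if samples and sample_idx is not None:
        sdata = rec.samples[samples[sample_idx]]
        raw_ad = sdata.get("AD")
        if raw_ad is not None and not all(a is None for a in raw_ad):
            ad = [0 if a is None else int(a) for a in raw_ad]
        raw_dp = sdata.get("DP")
        if raw_dp is not None:
            depth = int(raw_dp)
    if depth is None:
        info_dp = rec.info.get("DP")
        if info_dp is not None:
            depth = int(info_dp)
    if depth is None and ad is not None:
        depth = int(sum(ad))
    out = []
    for alt_idx, alt in enumerate(alts):
        if alt is None or alt in ("<NON_REF>", "*"):
            continue
        alt_count = None
        if ad is not None and len(ad) > alt_idx + 1:
            alt_count = ad[alt_idx + 1]
        d = depth
        if d is not None and alt_count is not None and alt_count > d:
            d = alt_count  # inconsistent caller output; trust the allele count
        v = VariantRecord(chrom=chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                          depth=d, alt_count=alt_count)
        out.append(normalize_variant(v))
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_vcf(records: Iterable[VariantRecord], path: str | Path,
              sample_name: str = "TUMOR") -> None:
    """Write records as a minimal sorted single-sample VCF 4.2 file."""
    records = sorted(records, key=lambda v: v.key)
    contigs = sorted({v.chrom for v in records})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for v in records:
            if v.depth is None or v.alt_count is None:
                fmt, val = "DP", "."
            else:
                ref_count = v.depth - v.alt_count
                fmt, val = "DP:AD", f"{v.depth}:{ref_count},{v.alt_count}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                     f"{fmt}\t{val}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

class GenomicRegionSet:
    """A named genomic stratum: merged, sorted 0-based half-open intervals."""

    def __init__(self, name: str,
                 intervals: Iterable[tuple[str, int, int]]) -> None:
        self.name = name
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_chrom[chrom] = ([m[0] for m in merged], [m[1] for m in merged])

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._by_chrom):
            starts, ends = self._by_chrom[chrom]
            out.extend((chrom, s, e) for s, e in zip(starts, ends))
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position against half-open intervals."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, pos - 1) - 1
        return i >= 0 and pos - 1 < ends[i]

    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenomicRegionSet)
                and self.name == other.name
                and self.intervals == other.intervals)

    def __repr__(self) -> str:
        return f"GenomicRegionSet({self.name!r}, {len(self.intervals)} intervals)"


@dataclass(frozen=True)
class CoverageBin:
    """Mean read depth over a 0-based half-open genomic bin."""

    chrom: str
    start: int
    end: int
    depth: float
    gc: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid bin {self.chrom}:{self.start}-{self.end}")
        if self.depth < 0 or math.isnan(self.depth):
            raise ValueError(f"negative or NaN depth in bin {self.chrom}:{self.start}")
        if self.gc is not None and not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc fraction out of [0,1]: {self.gc}")

    @property
    def width(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path, name: str | None = None,
             harmonize: bool = True,
             alias_map: Mapping[str, str] | None = None) -> GenomicRegionSet:
    """Read a BED3 file into a merged :class:`GenomicRegionSet`."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = normalize_chrom(parts[0], alias_map) if harmonize else parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            intervals.append((chrom, start, end))
    return GenomicRegionSet(name or path.stem, intervals)


def write_bed(regions: GenomicRegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bedgraph(path: str | Path, harmonize: bool = True,
                  alias_map: Mapping[str, str] | None = None) -> list[CoverageBin]:
    """Read a 4-column bedGraph into sorted, non-overlapping coverage bins."""
    path = Path(path)
    bins: list[CoverageBin] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = normalize_chrom(parts[0], alias_map) if harmonize else parts[0]
            try:
                start, end, depth = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            bins.append(CoverageBin(chrom, start, end, depth))
    bins.sort(key=lambda b: (b.chrom, b.start))
    prev: CoverageBin | None = None
    for b in bins:
        if prev is not None and b.chrom == prev.chrom and b.start < prev.end:
            raise ValueError(
                f"{path}: overlapping bins {prev.chrom}:{prev.start}-{prev.end} "
                f"and {b.chrom}:{b.start}-{b.end} (ambiguous depth)"
            )
        prev = b
    return bins


def write_bedgraph(bins: Iterable[CoverageBin], path: str | Path) -> None:
    bins = sorted(bins, key=lambda b: (b.chrom, b.start))
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.depth:g}\n")


def attach_gc(bins: Sequence[CoverageBin],
              gc_bins: Sequence[CoverageBin]) -> list[CoverageBin]:
    """Join a GC-fraction track (depth column holds GC) onto coverage bins.

    Bins are matched on exact (chrom, start, end); a coverage bin without a
    matching GC bin raises, since the dropout metrics require GC everywhere.
    """
    gc_map = {(g.chrom, g.start, g.end): g.depth for g in gc_bins}
    out = []
    for b in bins:
        gc = gc_map.get((b.chrom, b.start, b.end))
        if gc is None:
            raise ValueError(f"no GC value for bin {b.chrom}:{b.start}-{b.end}")
        out.append(replace(b, gc=gc))
    return out
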