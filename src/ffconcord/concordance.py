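"""FF-vs-FFPE variant-set concordance: tri-set partition, stratification,
allelic-fraction sweeps and the binomial detection-power filter.

Two somatic call sets from the same tumor (one fresh-frozen, one FFPE) are
compared by exact variant key. The union splits into FF-unique, FFPE-unique
and overlap; *agreement* is |overlap| / |union| (the three sections of the
pie sum to 100%), while *sensitivity* (|overlap| / |FF|) and *PPV*
(|overlap| / |FFPE|) treat the fresh-frozen set as reference.

Discordance driven by low-level variants is addressed by the power filter:
a variant whose allelic fraction is too low to be confidently detected at
the local depth in *either* specimen cannot be scored as a true
disagreement. Detection power is the binomial tail
``P(X >= k), X ~ Binomial(depth, af)`` with ``k`` the minimum number of
supporting reads a caller needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CoverageBin, GenomicRegionSet, VariantRecord

__all__ = [
    "ConcordancePartition",
    "PowerFilterConfig",
    "CoverageLookup",
    "combine_callers",
    "partition",
    "stratify_by_region",
    "af_sweep",
    "detection_power",
    "min_detectable_af",
    "power_filter",
]

VariantKey = tuple[str, int, str, str]


@dataclass
class ConcordancePartition:
    """The FF-unique / FFPE-unique / overlap tri-set with agreement stats.

    ``overlap`` holds the FF copy of each shared variant (so its evidence
    fields are the FF ones); ``overlap_ffpe`` keeps the FFPE counterparts
    for AF comparisons.
    """

    ff_unique: list[VariantRecord]
    ffpe_unique: list[VariantRecord]
    overlap: list[VariantRecord]
    overlap_ffpe: list[VariantRecord] = field(default_factory=list, repr=False)

    @property
    def n_ff(self) -> int:
        return len(self.ff_unique) + len(self.overlap)

    @property
    def n_ffpe(self) -> int:
        return len(self.ffpe_unique) + len(self.overlap)

    @property
    def n_union(self) -> int:
        return len(self.ff_unique) + len(self.ffpe_unique) + len(self.overlap)

    @property
    def agreement(self) -> float:
        return len(self.overlap) / self.n_union

    @property
    def sensitivity(self) -> float:
        """|overlap| / |FF|, fresh-frozen as reference; NaN when FF is empty."""
        return len(self.overlap) / self.n_ff if self.n_ff else float("nan")

    @property
    def ppv(self) -> float:
        return len(self.overlap) / self.n_ffpe if self.n_ffpe else float("nan")

    def summary(self) -> dict[str, float]:
        return {
            "n_ff": self.n_ff, "n_ffpe": self.n_ffpe, "n_union": self.n_union,
            "n_ff_unique": len(self.ff_unique),
            "n_ffpe_unique": len(self.ffpe_unique),
            "n_overlap": len(self.overlap),
            "agreement": self.agreement,
            "agreement_pct": 100.0 * self.agreement,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
        }


@dataclass
class PowerFilterConfig:
    """Thresholds of the detection-power filter.

    Defaults mirror the study design: strict depth > 70x required in both
    specimens and AF > 0.067 in at least one. ``min_alt_reads`` and
    ``target_power`` parameterize the binomial model behind those numbers
    (3 supporting reads, 90% power) and feed :func:`min_detectable_af`.
    """

    min_depth: int = 70
    min_af: float = 0.067
    min_alt_reads: int = 3
    target_power: float = 0.9

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.min_af < 1.0:
            raise ValueError("min_af must be in (0,1)")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0,1)")


def _key_map(variants: Iterable[VariantRecord],
             label: str) -> dict[VariantKey, VariantRecord]:
    out: dict[VariantKey, VariantRecord] = {}
    for v in variants:
        if v.key in out:
            raise ValueError(f"duplicate variant key {v.key} in {label} set")
        out[v.key] = v
    return out


def combine_callers(
    callsets: Sequence[Sequence[VariantRecord]],
) -> list[VariantRecord]:
    """High-confidence consensus: exact key intersection across callers.

    Evidence fields (depth, alt count) are taken from the first callset
    listed. Associative: combining incrementally equals combining at once.
    """
    if not callsets:
        raise ValueError("need at least one callset")
    maps = [_key_map(cs, f"caller {i}") for i, cs in enumerate(callsets)]
    keys = set(maps[0])
    for m in maps[1:]:
        keys &= set(m)
    return sorted((maps[0][k] for k in keys), key=lambda v: v.key)


def partition(ff: Sequence[VariantRecord],
              ffpe: Sequence[VariantRecord]) -> ConcordancePartition:
    """Key-wise tri-set partition of two normalized call sets.

    Raises when both sets are empty: agreement is then undefined and must
    not be silently reported as 0 or 1.
    """
    ff_map = _key_map(ff, "FF")
    ffpe_map = _key_map(ffpe, "FFPE")
    if not ff_map and not ffpe_map:
        raise ValueError("both call sets are empty; agreement is undefined")
    shared = sorted(set(ff_map) & set(ffpe_map))
    return ConcordancePartition(
        ff_unique=sorted((v for k, v in ff_map.items() if k not in ffpe_map),
                         key=lambda v: v.key),
        ffpe_unique=sorted((v for k, v in ffpe_map.items() if k not in ff_map),
                           key=lambda v: v.key),
        overlap=[ff_map[k] for k in shared],
        overlap_ffpe=[ffpe_map[k] for k in shared],
    )


def stratify_by_region(
    part: ConcordancePartition,
    strata: Sequence[GenomicRegionSet],
) -> dict[str, ConcordancePartition | None]:
    """Recompute the partition inside each genomic stratum.

    A variant belongs to every stratum whose (merged, half-open, 0-based)
    intervals contain its 1-based position; variants in no stratum are
    collected under ``"unstratified"``. Strata where both restricted sets
    are empty map to ``None``.
    """
    ff_all = part.ff_unique + part.overlap
    ffpe_all = part.ffpe_unique + part.overlap_ffpe

    def _restrict(variants, pred):
        return [v for v in variants if pred(v)]

    out: dict[str, ConcordancePartition | None] = {}
    for stratum in strata:
        ff_in = _restrict(ff_all, lambda v: stratum.contains(v.chrom, v.pos))
        ffpe_in = _restrict(ffpe_all, lambda v: stratum.contains(v.chrom, v.pos))
        out[stratum.name] = partition(ff_in, ffpe_in) if (ff_in or ffpe_in) else None

    def _nowhere(v) -> bool:
        return not any(s.contains(v.chrom, v.pos) for s in strata)

    ff_out = _restrict(ff_all, _nowhere)
    ffpe_out = _restrict(ffpe_all, _nowhere)
    out["unstratified"] = partition(ff_out, ffpe_out) if (ff_out or ffpe_out) else None
    return out


def af_sweep(ff: Sequence[VariantRecord], ffpe: Sequence[VariantRecord],
             thresholds: Sequence[float]) -> pd.DataFrame:
    """Agreement after removing low-AF variants at each threshold.

    For each threshold ``t`` variants with ``af < t`` are dropped from both
    sets independently and agreement is recomputed. Columns: threshold,
    agreement (fraction), agreement_pct, n_ff, n_ffpe, n_overlap. Thresholds
    that empty both sets yield NaN agreement (undefined, not 0).
    """
    for v in list(ff) + list(ffpe):
        if v.af is None:
            raise ValueError(f"variant {v.key} has undefined AF; "
                             "AF sweep requires AF everywhere")
    rows = []
    for t in thresholds:
        ff_t = [v for v in ff if v.af >= t]
        ffpe_t = [v for v in ffpe if v.af >= t]
        if not ff_t and not ffpe_t:
            rows.append({"threshold": t, "agreement": np.nan,
                         "agreement_pct": np.nan, "n_ff": 0, "n_ffpe": 0,
                         "n_overlap": 0})
            continue
        p = partition(ff_t, ffpe_t)
        rows.append({"threshold": t, "agreement": p.agreement,
                     "agreement_pct": 100.0 * p.agreement,
                     "n_ff": p.n_ff, "n_ffpe": p.n_ffpe,
                     "n_overlap": len(p.overlap)})
    return pd.DataFrame(rows)


def detection_power(depth: int, af: float, min_alt_reads: int) -> float:
    """P(X >= min_alt_reads) with X ~ Binomial(depth, af).

    The probability that a variant truly present at allelic fraction ``af``
    yields at least the required number of supporting reads at this depth.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= af <= 1.0:
        raise ValueError("af must be in [0,1]")
    if min_alt_reads < 0:
        raise ValueError("min_alt_reads must be >= 0")
    if min_alt_reads == 0:
        return 1.0
    return float(stats.binom.sf(min_alt_reads - 1, depth, af))


AF_GRID_STEP = 1e-4


def min_detectable_af(depth: int, min_alt_reads: int,
                      target_power: float) -> float:
    """Smallest AF on a 1e-4 grid whose detection power reaches the target.

    Monotone non-increasing in depth. Raises when even AF = 1 is
    underpowered (depth below the required read count).
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0,1)")
    grid = np.arange(1, int(round(1 / AF_GRID_STEP)) + 1) * AF_GRID_STEP
    power = stats.binom.sf(min_alt_reads - 1, depth, grid) \
        if min_alt_reads > 0 else np.ones_like(grid)
    idx = np.argmax(power >= target_power)
    if power[idx] < target_power:
        raise ValueError(
            f"no AF reaches power {target_power} at depth {depth} with "
            f"{min_alt_reads} required reads")
    return float(grid[idx])


class CoverageLookup:
    """Depth lookup from a coverage track for sites without a call record.

    Resolves a 1-based position to the depth of its containing bin, falling
    back to the nearest bin on the same chromosome (an approximation for
    positions just outside the binned span).
    """

    def __init__(self, bins: Sequence[CoverageBin]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[CoverageBin]] = {}
        for b in bins:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in by_chrom.items():
            bs.sort(key=lambda b: b.start)
            self._by_chrom[chrom] = (
                np.array([b.start for b in bs]),
                np.array([b.end for b in bs]),
                np.array([b.depth for b in bs]),
            )

    def depth_at(self, chrom: str, pos: int) -> float | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, depths = entry
        p0 = pos - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i >= 0 and p0 < ends[i]:
            return float(depths[i])
        # nearest bin by distance to its span
        cand = [j for j in (i, i + 1) if 0 <= j < len(starts)]
        if not cand:
            return None
        j = min(cand, key=lambda j: min(abs(p0 - starts[j]), abs(p0 - ends[j])))
        return float(depths[j])


def _resolve_evidence(
    key: VariantKey,
    own: Mapping[VariantKey, VariantRecord],
    coverage: CoverageLookup | None,
) -> tuple[float | None, float]:
    """(depth, af) for a variant key in one specimen; af is 0 when uncalled."""
    rec = own.get(key)
    if rec is not None and rec.depth is not None:
        return float(rec.depth), (rec.af if rec.af is not None else 0.0)
    if coverage is not None:
        d = coverage.depth_at(key[0], key[1])
        if d is not None:
            return d, 0.0
    return None, 0.0


def power_filter(
    ff: Sequence[VariantRecord],
    ffpe: Sequence[VariantRecord],
    config: PowerFilterConfig = PowerFilterConfig(),
    ff_coverage: CoverageLookup | Sequence[CoverageBin] | None = None,
    ffpe_coverage: CoverageLookup | Sequence[CoverageBin] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord], ConcordancePartition]:
    """Drop variants underpowered in either specimen, then re-partition.

    A variant key survives iff depth exceeds ``min_depth`` in *both*
    specimens (strict, as the thresholds are stated) and its AF exceeds
    ``min_af`` in at least one. Depth in a specimen where the variant was
    not called is read from that specimen's coverage track at the position
    of the variant (nearest containing bin - an approximation, since
    callers emit no site record there). Keys whose cross-sample depth
    cannot be resolved raise, listing the offending keys.
    """
    if ff_coverage is not None and not isinstance(ff_coverage, CoverageLookup):
        ff_coverage = CoverageLookup(ff_coverage)
    if ffpe_coverage is not None and not isinstance(ffpe_coverage, CoverageLookup):
        ffpe_coverage = CoverageLookup(ffpe_coverage)
    ff_map = _key_map(ff, "FF")
    ffpe_map = _key_map(ffpe, "FFPE")
    missing: list[VariantKey] = []
    keep: set[VariantKey] = set()
    for key in set(ff_map) | set(ffpe_map):
        d_ff, af_ff = _resolve_evidence(key, ff_map, ff_coverage)
        d_ffpe, af_ffpe = _resolve_evidence(key, ffpe_map, ffpe_coverage)
        if d_ff is None or d_ffpe is None:
            missing.append(key)
            continue
        if (d_ff > config.min_depth and d_ffpe > config.min_depth
                and (af_ff > config.min_af or af_ffpe > config.min_af)):
            keep.add(key)
    if missing:
        shown = ", ".join(map(str, sorted(missing)[:5]))
        raise ValueError(
            f"{len(missing)} variant keys lack cross-sample depth and no "
            f"coverage track was supplied (first: {shown})")
    ff_kept = sorted((v for k, v in ff_map.items() if k in keep),
                     key=lambda v: v.key)
    ffpe_kept = sorted((v for k, v in ffpe_map.items() if k in keep),
                       key=lambda v: v.key)
    return ff_kept, ffpe_kept, partition(ff_kept, ffpe_kept)
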