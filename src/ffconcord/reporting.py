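"""Clinical-report tiering and the FF-vs-FFPE report overlap table.

Alterations (small variants and gene-level copy-number calls) are assigned
actionability tiers from a plain-text rules table (gene, alteration class,
tier 1-3); tier 1 marks clinically actionable findings (druggable,
predictive/prognostic or diagnostic). Reports generated independently from
the fresh-frozen and FFPE data of each case are then compared per tier:
how many alterations were reported from both specimens, and how many were
missed in one of them.

Small variants match on their exact variant key; copy-number alterations
match at gene level by (gene, direction), since clinical CNA reporting is
gene-centric and exact breakpoints are not reproducible between specimens.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FUNCTIONAL_CONSEQUENCES",
    "Alteration",
    "ReportedAlteration",
    "TierRules",
    "TierReportTable",
    "consequence_filter",
    "assign_tiers",
    "build_report_table",
    "read_report_tsv",
    "round_half_up",
]

KINDS = ("SNV_indel", "CNA")

#: consequence terms kept by the functional filter: exonic missense, stop
#: gain/loss, frameshift and in-frame indels, and splicing variants.
FUNCTIONAL_CONSEQUENCES = frozenset({
    "missense", "missense_variant",
    "stop_gained", "stop_lost",
    "frameshift", "frameshift_variant",
    "inframe_insertion", "inframe_deletion", "inframe_indel",
    "splicing", "splice_acceptor_variant", "splice_donor_variant",
    "splice_region_variant",
})


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero-half (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Alteration:
    """One reportable finding before tier assignment.

    ``variant_key`` is the normalized chrom:pos:ref:alt string for small
    variants and the direction (``gain``/``loss``) for CNAs.
    """

    case_id: str
    gene: str
    kind: str
    variant_key: str = ""
    consequence: str | None = None
    af: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    @property
    def identity(self) -> tuple[str, str, str, str]:
        return (self.case_id, self.gene, self.kind, self.variant_key)


@dataclass(frozen=True)
class ReportedAlteration(Alteration):
    tier: int = 0
    present_in: str | None = None       # FF_only / FFPE_only / both


class TierRules:
    """Gene -> actionability tier lookup with class-specific overrides.

    Rows are (gene, alteration_class in {SNV_indel, CNA, any}, tier in 1-3);
    a class-specific row wins over an ``any`` row for the same gene.
    Duplicate (gene, class) pairs are rejected at load.
    """

    def __init__(self, entries: Iterable[tuple[str, str, int]]) -> None:
        self._rules: dict[tuple[str, str], int] = {}
        for gene, alt_class, tier in entries:
            if alt_class not in (*KINDS, "any"):
                raise ValueError(f"unknown alteration class {alt_class!r}")
            tier = int(tier)
            if tier not in (1, 2, 3):
                raise ValueError(f"tier must be 1-3, got {tier}")
            key = (gene, alt_class)
            if key in self._rules:
                raise ValueError(f"duplicate tier rule for {key}")
            self._rules[key] = tier

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TierRules":
        entries = []
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "gene":
                    continue
                if len(row) < 3:
                    raise ValueError(f"{path}: expected 3 columns, got {row}")
                entries.append((row[0], row[1], int(row[2])))
        return cls(entries)

    def tier_for(self, gene: str, kind: str) -> int | None:
        return self._rules.get((gene, kind), self._rules.get((gene, "any")))

    def __len__(self) -> int:
        return len(self._rules)


def consequence_filter(alterations: Sequence[Alteration]) -> list[Alteration]:
    """Keep alterations with a functional consequence (CNAs always pass).

    Small variants require an annotated consequence from
    :data:`FUNCTIONAL_CONSEQUENCES`; unannotated or non-functional (e.g.
    intergenic, synonymous) small variants are dropped.
    """
    kept = []
    for a in alterations:
        if a.kind == "CNA":
            kept.append(a)
        elif a.consequence is not None and \
                a.consequence.lower() in FUNCTIONAL_CONSEQUENCES:
            kept.append(a)
    return kept


def assign_tiers(alterations: Sequence[Alteration],
                 rules: TierRules) -> list[ReportedAlteration]:
    """Tier every alteration; genes absent from the rules are excluded."""
    out = []
    for a in alterations:
        tier = rules.tier_for(a.gene, a.kind)
        if tier is None:
            continue
        out.append(ReportedAlteration(
            case_id=a.case_id, gene=a.gene, kind=a.kind,
            variant_key=a.variant_key, consequence=a.consequence, af=a.af,
            tier=tier))
    return out


_COUNT_COLS = [
    "total_snv", "total_cna",
    "unique_ff_snv", "unique_ff_cna",
    "unique_ffpe_snv", "unique_ffpe_cna",
    "overlap_snv", "overlap_cna",
]


@dataclass
class TierReportTable:
    """Per-(case, tier) overlap counts between FF and FFPE clinical reports.

    ``data`` rows are keyed by (case_id, tier) with per-category counts
    split into small variants (``_snv``) and CNAs (``_cna``), plus derived
    totals and rounded percent-overlap columns; ``Total`` rows sum the case
    rows per tier.
    """

    data: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Report-style strings: 'Total (snv/cna)' counts and 'pct (snv/cna)'."""

        def cell(row, prefix):
            s, c = row[f"{prefix}_snv"], row[f"{prefix}_cna"]
            return f"{s + c} ({s}/{c})"

        def pct_cell(row):
            def pct(num, den):
                return str(round_half_up(100.0 * num / den)) if den else "NA"
            total = row["total_snv"] + row["total_cna"]
            overlap = row["overlap_snv"] + row["overlap_cna"]
            return (f"{pct(overlap, total)} "
                    f"({pct(row['overlap_snv'], row['total_snv'])}/"
                    f"{pct(row['overlap_cna'], row['total_cna'])})")

        rows = []
        for _, row in self.data.iterrows():
            rows.append({
                "Sample": row["case_id"], "Tier": row["tier"],
                "Total": cell(row, "total"),
                "Unique FF": cell(row, "unique_ff"),
                "Unique FFPE": cell(row, "unique_ffpe"),
                "Overlap": cell(row, "overlap"),
                "% Overlap": pct_cell(row),
            })
        return pd.DataFrame(rows, columns=["Sample", "Tier", "Total",
                                           "Unique FF", "Unique FFPE",
                                           "Overlap", "% Overlap"])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def build_report_table(ff_report: Sequence[ReportedAlteration],
                       ffpe_report: Sequence[ReportedAlteration]
                       ) -> TierReportTable:
    """Cross the two specimen reports into the per-tier overlap table.

    Alterations match on (case, gene, kind, variant key); the tier of an
    overlapping alteration is taken from the FF report. Percent overlap is
    rounded half-up to an integer. Empty reports give an empty table.
    """
    ff_map = {a.identity: a for a in ff_report}
    ffpe_map = {a.identity: a for a in ffpe_report}
    if len(ff_map) != len(ff_report):
        raise ValueError("duplicate alteration identities in FF report")
    if len(ffpe_map) != len(ffpe_report):
        raise ValueError("duplicate alteration identities in FFPE report")

    counts: dict[tuple[str, int], dict[str, int]] = {}

    def bucket(case_id: str, tier: int) -> dict[str, int]:
        return counts.setdefault((case_id, tier),
                                 {c: 0 for c in _COUNT_COLS})

    for ident in sorted(set(ff_map) | set(ffpe_map)):
        a = ff_map.get(ident) or ffpe_map[ident]
        suffix = "snv" if a.kind == "SNV_indel" else "cna"
        b = bucket(a.case_id, a.tier)
        b[f"total_{suffix}"] += 1
        if ident in ff_map and ident in ffpe_map:
            b[f"overlap_{suffix}"] += 1
        elif ident in ff_map:
            b[f"unique_ff_{suffix}"] += 1
        else:
            b[f"unique_ffpe_{suffix}"] += 1

    if not counts:
        cols = ["case_id", "tier", *_COUNT_COLS, "total", "overlap",
                "percent_overlap"]
        return TierReportTable(data=pd.DataFrame(columns=cols))

    rows = []
    # numeric case ids sort numerically so table order matches the cohort
    cases = sorted({c for c, _ in counts},
                   key=lambda c: (0, int(c), "") if c.isdigit() else (1, 0, c))
    tiers = sorted({t for _, t in counts})
    for case_id in cases:
        for tier in tiers:
            if (case_id, tier) in counts:
                rows.append({"case_id": case_id, "tier": tier,
                             **counts[(case_id, tier)]})
    for tier in tiers:
        total_row = {c: 0 for c in _COUNT_COLS}
        for case_id in cases:
            for col in _COUNT_COLS:
                total_row[col] += counts.get((case_id, tier), {}).get(col, 0)
        rows.append({"case_id": "Total", "tier": tier, **total_row})

    df = pd.DataFrame(rows)
    df["total"] = df["total_snv"] + df["total_cna"]
    df["overlap"] = df["overlap_snv"] + df["overlap_cna"]
    df["percent_overlap"] = [
        round_half_up(100.0 * o / t) if t else pd.NA
        for o, t in zip(df["overlap"], df["total"])
    ]
    return TierReportTable(data=df)


def read_report_tsv(path: str | Path) -> list[Alteration]:
    """Read a per-case report TSV with columns case_id, gene, kind,
    variant_key, consequence, af."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["case_id"].startswith("#"):
                continue
            af = row.get("af")
            out.append(Alteration(
                case_id=row["case_id"], gene=row["gene"], kind=row["kind"],
                variant_key=row.get("variant_key", "") or "",
                consequence=row.get("consequence") or None,
                af=float(af) if af not in (None, "", "NA") else None,
            ))
    return out
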