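"""Tier a pair of case reports and build the FF-vs-FFPE overlap table.

Alterations are tiered from a rules table (tier 1 = clinically actionable);
the table counts, per case and tier, how many were reported from both
specimens versus only one, with small-variant / CNA splits.
"""

from ffconcord import (
    Alteration,
    TierRules,
    assign_tiers,
    build_report_table,
    consequence_filter,
)

# demo rules table - synthetic, not clinical guidance
rules = TierRules([
    ("VHL", "any", 1), ("MET", "CNA", 1), ("PBRM1", "any", 2),
    ("SETD2", "any", 2), ("BAP1", "any", 3),
])

ff = [
    Alteration("case1", "VHL", "SNV_indel", "3:10191:C:T", "frameshift", 0.45),
    Alteration("case1", "MET", "CNA", "gain"),
    Alteration("case1", "PBRM1", "SNV_indel", "3:52584:G:A", "missense", 0.31),
    Alteration("case1", "BAP1", "SNV_indel", "3:52440:T:C", "missense", 0.08),
]
ffpe = [
    Alteration("case1", "VHL", "SNV_indel", "3:10191:C:T", "frameshift", 0.41),
    Alteration("case1", "MET", "CNA", "gain"),
    Alteration("case1", "SETD2", "SNV_indel", "3:47059:C:A", "stop_gained", 0.12),
]

table = build_report_table(
    assign_tiers(consequence_filter(ff), rules),
    assign_tiers(consequence_filter(ffpe), rules),
)
print(table.formatted().to_string(index=False))
print()
print("Counts are 'total (small-variant/CNA)'; %Overlap is the share of the")
print("tier's alterations reported from both specimens (NA: empty category).")
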