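"""Canonicalize and element-filter a small multi-source record set.

Builds a handful of toxicity records (including a carbon-free acid and an
organomercury compound), canonicalizes the SMILES, and applies the
13-element whitelist filter, printing what was removed and why.
"""

from toxforge import ToxRecord, Units, canonicalize_records, element_filter

raw = [
    ToxRecord("OCC", "rat_oral_ld50", 1.2, Units.LOG10_MMOL_PER_KG, "toxric"),
    ToxRecord("CCO", "rat_oral_ld50", 1.1, Units.LOG10_MMOL_PER_KG, "pubchem"),
    ToxRecord("O=S(=O)(O)O", "rat_oral_ld50", 0.3, Units.LOG10_MMOL_PER_KG, "toxric"),
    ToxRecord("CC[Hg]CC", "rat_oral_ld50", -2.0, Units.LOG10_MMOL_PER_KG, "pubchem"),
    ToxRecord("c1ccccc1N", "rat_oral_ld50", 0.5, Units.LOG10_MMOL_PER_KG, "efsa"),
]

canonical, failed = canonicalize_records(raw)
kept, removed = element_filter(canonical)

print(f"{len(raw)} records in, {len(kept)} kept")
for rec in kept:
    print(f"  kept    {rec.smiles:12s} from {rec.source_id}")
for rm in removed:
    print(f"  removed {rm.record.smiles:12s} reason={rm.reason}")
# Note OCC and CCO now share one canonical SMILES: the duplicate is visible
# to the aggregation step, which is the point of canonicalizing first.
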