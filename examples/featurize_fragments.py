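"""Fragment-count featurization with the full filtering cascade.

Counts toxicophore-library fragments over 200 synthetic molecules, then
applies the cascade — drop fragments occurring in <1% of molecules, drop
fragments with mean count <0.025 per molecule, prune Pearson |r|>0.85
pairs — and joins whole-molecule descriptors with non-zero frequency ≥2.5%.
"""

from toxforge import FilterConfig, default_catalog, featurize, gen_molecules

molecules = gen_molecules(200, seed=5)
matrix, report = featurize(molecules, default_catalog(), FilterConfig())

print(f"catalog size: {len(default_catalog())} fragment patterns")
for stage, removed in report.stages.items():
    print(f"  stage {stage:11s}: removed {len(removed)}")
print(f"final matrix: {matrix.shape[0]} molecules × {matrix.shape[1]} features")
frags = [c for c in matrix.columns if c in default_catalog().fragment_ids()]
print(f"  of which fragment counts: {len(frags)} (e.g. {frags[:5]})")
print("each surviving column is a count (fragments) or descriptor value,")
print("with removal reasons recorded per stage in the FilterReport")
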