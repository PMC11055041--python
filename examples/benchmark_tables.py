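"""Cross-model win counting on the shipped benchmark tables.

Loads the transcribed per-target five-fold-CV metric tables (29 regression
targets with RMSE, 22 classification targets with ROC AUC) and counts how
often the fragment-based XGBoost model strictly beats both the fingerprint
CatBoost model and the published benchmark.
"""

from toxforge import (
    compare_models, count_rows_above, load_paper_tables, metric_size_profile,
)

regression, classification = load_paper_tables()

tox21 = [t for t in classification.frame["target"] if t.startswith(("NR-", "SR-"))]
r = compare_models(
    classification, "xgb_fragments", ["catboost_fp", "benchmark"], rows=tox21
)
print(f"Tox21 assays: fragment model wins {r.wins} of {r.total}")

r = compare_models(classification, "xgb_fragments", ["catboost_fp", "benchmark"])
print(f"all classification targets: {r.wins} of {r.total} ({r.percent}%)")

n_large = count_rows_above(regression, 10_000)
print(f"regression targets with >10,000 samples: {n_large} of {len(regression)}")

profile = metric_size_profile(regression, "xgb_fragments")
lo, hi = profile[0], profile[-1]
print(f"RMSE vs size: {lo[1]:.3f} at n={lo[0]} → {hi[1]:.3f} at n={hi[0]}")
print("(sorted pairs ready for a log-scale sample-size plot)")
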