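"""End-to-end QSAR evaluation on synthetic data with a planted toxicophore.

Molecules containing a nitro group get a 2-log lower lethal dose.  The
pipeline aggregates the multi-source records, builds fragment features, and
five-fold cross-validates a ridge regression (through the scikit-learn
adapter) against a mean-predictor baseline; the fragment counts carry the
planted signal, so the feature-based model wins clearly.
"""

from sklearn.linear_model import Ridge

from toxforge import (
    EndpointSpec, EvalConfig, MeanLearner, SklearnLearner,
    SyntheticConfig, Task, Units, aggregate_regression, cross_validate,
    featurize, gen_regression_records,
)

cfg = SyntheticConfig(n_molecules=300, n_sources=3, noise_sd=0.2, seed=1)
records, _ = gen_regression_records(
    cfg, planted_smarts="[NX3+](=O)[O-]", planted_effect=-2.0
)
endpoint = EndpointSpec(
    "ld50_synthetic", Task.REGRESSION, Units.LOG10_MMOL_PER_KG
)
dataset = aggregate_regression(records, endpoint)
features, _ = featurize(dataset.smiles, include_descriptors=False)

eval_cfg = EvalConfig(k_folds=5, seed=0)
ridge = cross_validate(
    features, dataset.values, lambda: SklearnLearner(Ridge(alpha=1.0)),
    Task.REGRESSION, eval_cfg,
)
mean = cross_validate(
    features, dataset.values, MeanLearner, Task.REGRESSION, eval_cfg
)

print(f"{len(dataset)} molecules, {features.shape[1]} fragment features, 5-fold CV")
print(f"mean predictor RMSE  : {mean.mean:.3f} ± {mean.sd:.3f}")
print(f"ridge fragments RMSE : {ridge.mean:.3f} ± {ridge.sd:.3f}")
print("lower RMSE for the feature-based model shows the planted")
print("nitro-toxicity signal is recoverable from the fragment counts")
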