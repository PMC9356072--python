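"""The full experiment protocol: split, CV model selection, test report.

Runs the seeded 80/20 split and 5-fold cross-validation over a small
hyperparameter grid (number of mRMR-selected genes), refits the winning
configuration on the full training set and reports held-out test metrics.
Feature selection is refit inside every fold so no validation information
leaks into the gene ranking.
"""

from sauronrf import CVConfig, GridPoint, ModelSpec, SimConfig, generate, run_experiment

ds = generate(SimConfig(n_samples=300, n_genes=60, n_informative=10, frac_sensitive=0.12, seed=5))
cv = CVConfig(
    test_fraction=0.2,
    n_folds=5,
    grid=[GridPoint(n_features=k, B=50, min_samples_leaf=5) for k in (10, 20, 40)],
    seed=5,
)
spec = ModelSpec(kind="sauron", sample_weighting="simple", tree_weighting="binary_sens")
res = run_experiment(ds, spec, cv)

print("CV mean MCC per grid point:")
for point, score in res.cv_scores.items():
    print(f"  {point}: {score:.3f}")
print(f"\nchosen: {res.chosen}")
print(f"first 5 selected genes: {res.selected_genes[:5]}")
rep = res.report
print(f"test sensitivity {rep.sensitivity:.2f}, specificity {rep.specificity:.2f}, MCC {rep.mcc:.2f}")
print(f"test MSE: sensitive {rep.mse_sens:.2f}, resistant {rep.mse_res:.2f}")
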