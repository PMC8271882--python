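"""End-to-end action recognition on a small synthetic Mocap dataset.

Generates 3 action classes x 2 subjects x 3 repetitions of articulated
skeleton motion, summarizes each record by a spectral-clustering codebook
with a PCA latent view, compares records with the joint-embedding metric
and evaluates a dissimilarity-space SVM by stratified cross-validation
(nested bandwidth/SVM grid search inside every training fold).
"""

from ehecco import (
    GeneratorConfig,
    PipelineConfig,
    cross_validate,
    dataset_from_synthetic,
    generate_dataset,
    variance_preserved,
)

generator = GeneratorConfig(
    n_classes=3, n_subjects=2, reps_per_cell=3, frame_rate=60.0,
    duration_range=(1.5, 2.5), seed=0,
)
config = PipelineConfig(n_clusters=20, q=3, seed=0, inner_folds=2, folds=6)

synth = generate_dataset(generator)
dataset = dataset_from_synthetic(synth, config)
print(f"records: {len(dataset)}  codebook: {config.n_clusters} poses x "
      f"{dataset.codebooks[0].shape[1]} coordinates")
print(f"latent space keeps {100 * variance_preserved(dataset.basis):.1f}% "
      f"of pooled pose variance in Q={config.q} components")

report = cross_validate(dataset, config=config)
print(f"\nmean CV accuracy: {report.mean_accuracy:.3f} over "
      f"{len(report.fold_accuracies)} folds")
print("confusion matrix (rows = true class):")
print(report.confusion)
print("\nfold 1 chose:", report.chosen_hyperparameters[0])
print("\nAn accuracy near 1.0 means the joint metric places same-action")
print("records close together regardless of subject style and duration.")
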