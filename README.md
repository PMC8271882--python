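# ehecco — joint-distribution kernel metric for motion-capture time series

`ehecco` compares multichannel time series — motion-capture (Mocap)
recordings of human movement — as **joint probability distributions
embedded in a tensor reproducing-kernel Hilbert space**, and builds a full
skeletal action/style recognition and interpretation pipeline on top of
that metric. It is aimed at researchers in human movement analysis,
biomechanics and time-series pattern recognition who want a
distribution-level distance between recordings of different lengths,
together with classification, visualization and covariate-correlation
tooling.

## The metric

A record is summarized as paired samples from two views: codebook poses
`x_n ∈ R^V` (flattened, hip-normalized 3-D joint coordinates, `V = 3J`)
and their PCA latent coordinates `y_n ∈ R^Q`, with a probability weight
vector `α` (uniform `1/N_c` by default). The joint law `P_{X,Y}` is
embedded in the tensor RKHS `H ⊗ G` through its cross-covariance operator
`μ_{H⊗G} = E[φ(x) ⊗ ψ(y)]`, and two records are compared by the squared
RKHS distance between their embeddings. By the kernel trick that distance
never materializes the embeddings; with Gaussian kernels `κ_φ` (bandwidth
`σ_φ`, primary space) and `κ_ψ` (bandwidth `σ_ψ`, latent space) the sample
estimator is

```
d²(P, R) = α_P' (K^φ_xx ∘ K^ψ_yy) α_P  +  α_R' (K^φ_zz ∘ K^ψ_ll) α_R
           − 2 α_P' (K^φ_xz ∘ K^ψ_yl) α_R
```

where `∘` is the Hadamard product — the tensor-product kernel evaluated on
paired samples. With an all-ones latent kernel and uniform weights the
expression collapses to the classical (biased) MMD estimator between the
primary-space marginals; the extra factor is exactly what makes the metric
sensitive to the *dependence* between the two views, not just their
marginals.

Around the metric, the pipeline is: BVH parsing → forward kinematics →
hip normalization → per-record spectral-clustering codebook (`N_c` medoid
poses) → global PCA latent view (`Q = 3`) → pairwise distance matrix `D` →
RBF-SVM in the dissimilarity space (features = rows of `D`) with nested
grid search over bandwidth multipliers `{0.5, 1, 2, 5, 10}·σ₀` (median
heuristic per space), SVM penalty `{1, 10, 10², 10³, 10⁴}` and precision
`{0.01, 0.1, 1, 100, 1000}` — evaluated by stratified 10-fold
cross-validation. `D` also feeds t-SNE views and an anthropometric
correlation analysis. A built-in synthetic articulated-skeleton generator
with closed-form kinematics provides labeled multi-class, multi-subject
data with known ground truth for every stage.

## Worked example

`examples/01_joint_metric_basics.py` draws paired samples with `Y = +X`
for one law and `Y = −X` for another — identical standard-normal marginals
in every coordinate, opposite coupling:

```
joint distance^2, same law        : 0.01100
joint distance^2, opposite coupling: 0.24498
marginal MMD^2 on X alone          : 0.00003
```

The joint metric separates the laws by more than an order of magnitude
over its within-law sampling noise, while the marginal MMD cannot see the
difference at all. `examples/02_recognition_pipeline.py` runs the full
recognition pipeline on a small generated dataset (3 actions × 2 subjects
× 3 repetitions):

```
latent space keeps 88.8% of pooled pose variance in Q=3 components
mean CV accuracy: 1.000 over 6 folds
confusion matrix (rows = true class):
[[6 0 0]
 [0 6 0]
 [0 0 6]]
```

and `examples/03_embedding_and_covariates.py` reproduces the
interpretation study — 17 subjects whose posture style determines a
height-like covariate:

```
|Pearson r| of covariates vs mean 1-D projection per subject:
height_cm              0.930
age_years              0.186
sitting_height_cm      0.195
thigh_perimeter_cm     0.236
triceps_skinfold_mm    0.084
```

Only the style-linked column correlates with the learned geometry; the
independent distractors stay at the 17-subject null level (~0.2).

## Command line

The same stages are available as a thin CLI:

```bash
ehecco simulate data/ --classes 5 --subjects 4 --reps 5 --seed 0
ehecco classify data/ report.json --confusion-csv confusion.csv
ehecco distmat data/ D.csv && ehecco embed D.csv tsne.csv --plot tsne.png
ehecco correlate D.csv data/labels.csv data/covariates.csv corr.csv
```

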