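# Methods

## The model

Two records are compared as joint probability distributions over a pair of
views. For a record with codebook poses `{x_n ∈ R^V}` and latent
coordinates `{y_n ∈ R^Q}` (the same `N_c` items in both views), the
empirical joint law is `Σ_n α_n δ(x − x_n, y − y_n)` with a probability
vector `α` (uniform `1/N_c` unless the caller supplies weights). The law
is mapped into the tensor RKHS `H ⊗ G` by its cross-covariance operator
`E[φ(x) ⊗ ψ(y)]`, where `φ`, `ψ` are the feature maps of Gaussian kernels
on the two spaces, and the squared distance between two records is the
squared tensor-space norm of the difference of their embeddings. Expanding
the norm and applying the kernel trick yields the three-term
Hadamard-product estimator implemented in `ehecco.metric.ehecco_squared`;
a nested-loop transcription (`ehecco_squared_oracle`) is kept as an
independent oracle and the two are required to agree to 1e−10 relative on
hundreds of random instances.

Properties relied on downstream, all enforced by tests:

- **metric axioms** — symmetry to 1e−12, zero self-distance, and
  non-negativity (the raw value is a squared norm; values in (−1e−9, 0)
  are clamped to 0 as round-off, anything below −1e−9 raises an error
  because it can only indicate a broken kernel);
- **reduction law** — an all-ones latent kernel with uniform weights
  collapses the estimator to the biased marginal-MMD estimator, tying the
  implementation to the classical quantity it generalizes;
- **joint sensitivity** — laws with identical marginals but opposite
  coupling (`Y = +X` vs `Y = −X`) are separated while marginal MMD stays
  at its permutation null.

Assumptions: Gaussian (characteristic) kernels on both spaces; both
records' views must share dimensions `V` and `Q`; the latent coordinates
of different records must live in one common basis (see below). The
estimator is the biased V-statistic form — self-pairs are included — which
keeps it a squared norm (non-negative) at the cost of an `O(1/N)` bias
that is immaterial for ranking distances.

## Kernels and bandwidths

All kernels are Gaussian, `exp(−‖a−b‖²/2σ²)`, computed via the stable
expansion `‖a‖² + ‖b‖² − 2a·b` with negative round-off clamped before
exponentiation. Bandwidths are data-driven: the *median heuristic* σ₀ is
the median of all distinct pairwise Euclidean distances (self-pairs
excluded — including their zeros would bias σ₀ down). Coincident data
(median 0) falls back to σ = 1 with a warning rather than an error so
degenerate synthetic edge cases keep running. Classification refines σ₀
over the multiplier grid {0.5, 1, 2, 5, 10}, separately per space.

The marginal MMD estimator evaluates its kernels at a doubled scale; both
readings of "doubled" are implemented (`convention="bandwidth"`, effective
bandwidth 2σ, the default; `"variance"`, effective bandwidth √2·σ) plus
`"none"`. The joint estimator applies `σ_φ`, `σ_ψ` as given.

## Pipeline

1. **Forward kinematics and normalization.** BVH channels are composed
   down the joint tree (offset translation, then channels in declared
   order; rotations intrinsic, degrees). End Sites carry no channels and
   are excluded from features. Normalization subtracts the root (hip)
   position per frame — translation only, no orientation alignment or
   limb rescaling, so body-size information survives for the covariate
   analysis. Coordinates stay in file units.
2. **Codebook.** Per record, frames are clustered with normalized spectral
   clustering: Gaussian affinity at the median-heuristic bandwidth,
   symmetric normalized Laplacian, bottom-`N_c` eigenvectors
   row-normalized, seeded k-means. Each cluster contributes its *medoid*
   (ties → lowest frame index), so codebook poses are actual recorded
   frames. Default `N_c = min(50, T)`: a few dozen poses cover cyclic
   movements while keeping the per-pair metric cost `O(N_c²)`.
3. **Latent view.** PCA with `Q = 3` fitted on the *pooled* codebook
   frames of the training records and applied to every record. A global
   basis is the only choice that makes the cross-record latent kernel
   meaningful — per-record bases differ by rotations and signs, which
   would make `κ_ψ(y, l)` compare incommensurable coordinates. Components
   follow a deterministic sign convention (largest-magnitude coefficient
   positive). On the default synthetic data three components retain ≥ 75%
   of pooled variance (measured ~83–87%).
4. **Classification.** The Λ×Λ distance matrix `D` stores the distance
   (square root of the clamped squared estimator) rather than its square —
   t-SNE and dissimilarity features behave better with a distance-like
   quantity; a flag exposes squared values. The SVM is trained in the
   dissimilarity space: record i's feature vector is row i of `D_train`,
   under an RBF kernel (a precomputed-kernel mode `exp(−γD²)` is available
   behind `svm_mode="kernel"`). Evaluation is stratified k-fold (default
   10, reduced with a warning when a class is smaller); *inside every
   training fold* the latent basis, the per-space σ₀ and the full
   5×5×5×5 hyperparameter grid (scored by internal stratified CV, default
   3 folds, ties → smallest grid indices) are derived from training
   records only. Accuracy is trace(confusion)/Λ; the confusion matrix is
   pooled over folds.

### Fast path

With equal codebook sizes and uniform weights the whole Λ×Λ matrix reduces
to block sums of one stacked tensor-product kernel matrix. The pipeline
caches the stacked squared-distance matrices of both spaces in float32, so
every bandwidth pair in the grid costs a single `exp` pass plus a reshape
sum (~0.3 s at Λ=100, N_c=50). The float64 estimator remains the reference
implementation; the fast path is tested against the brute-force oracle per
entry. Cross-validating 100 records takes ~2 min on one CPU; these sizes
(5 classes × 4 subjects × 5 repetitions, N_c = 50) are the package's
benchmark conditions.

## Visualization and covariate analysis

t-SNE runs in precomputed-distance mode. Two defaults deviate from common
practice for a documented reason: the optimization is initialized from
classical MDS of `D` (scaled to the conventional 1e−4 spread) rather than
randomly, and early exaggeration is 4 instead of 12. The covariate
analysis reads *coordinates* off a 1-D embedding, and with random starts
or strong exaggeration the 1-D embedding fragments and reorders subjects
unpredictably even when the distance geometry carries the signal at
r ≈ 0.99. Informative initialization with mild exaggeration is the
standard remedy for preserving global structure; both knobs remain
exposed (`init="random"`, `early_exaggeration=`).

The anthropometric analysis embeds `D` in one dimension, averages each
subject's record coordinates, and reports the absolute Pearson correlation
against every covariate column (constant columns yield a warning and a
missing value). Per-class tables and the full covariate-vs-covariate
matrix are also produced. For subject-level questions the perplexity must
exceed the per-subject record count — otherwise each subject's records
saturate their own neighborhood and subjects are placed arbitrarily —
so these analyses use 2.5× the per-subject count (15 for the 17-subject
study with 6 records each).

## Synthetic generator

Rotation channels follow closed-form sums of sinusoids, so every record
has an analytic ground truth: a large shared postural-sway factor (20° at
0.4 Hz along a fixed channel direction — one dominant motion factor, which
is what concentrates pose variance in few principal components, as real
movement does), a class component (offsets sd 8°, amplitudes sd 3°,
phases sd 0.7 rad, frequency sd 0.25 Hz around 1 Hz — all scaled by
`class_separation`, 0 removes class structure entirely), a subject style
(scalar ~N(0,1) shifting offsets along a fixed direction, 3° per unit
`style_scale`), and per-frame Gaussian jitter (`noise_sd`, default 1°).
Durations are drawn uniformly (default 2–4 s at 120 Hz) so lengths vary;
the root translates along a deterministic slow drift so hip normalization
is always exercised. Seeds are hierarchical: per-class, per-subject and
per-record streams derive from the master seed, so subsetting a dataset
never changes surviving records.

Each subject's covariate row contains one size-like column with known
linear style dependence (height = 170 + 9·style + N(0, 1.2) cm) and four
independent Gaussian distractors with anthropometric-style names. A
coupled-pair mode emits two classes whose right-arm channels mirror the
left arm either in phase or in anti-phase — identical per-channel
marginals, opposite inter-limb coupling — the Mocap analogue of the
`Y = ±X` fixture.

The 17-subject correlation study uses 2 classes × 17 subjects × 3
repetitions with `style_scale = 4` (posture dominates the between-record
geometry; that is the condition under which reading morphology off the
learned representation is a well-posed question).

What passing on this generator shows: the estimator implements its
definition exactly, the pipeline extracts class structure that is present
and refuses structure that is absent (chance level at separation 0), and
the geometry exposes a subject-level factor when one dominates. What it
does not show: robustness to marker noise, occlusion and retargeting
artifacts of real optical capture, to non-stationary or non-cyclic
actions, or to class structure expressed through dynamics the sinusoid
family cannot represent. Benchmark accuracies on real corpora cannot be
inferred from the synthetic numbers.

## Numerical choices

- Clamp threshold −1e−9 separates round-off from genuine inconsistency.
- Self-kernel matrices are symmetrized by averaging with their transpose;
  cross-kernel matrices never are.
- PCA ratios are relative to total variance; requesting `q` above the
  centered-data rank raises an error naming the achievable rank.
- Medoid ties and grid-search ties break deterministically (lowest index).
- One master seed fixes codebook k-means, fold shuffling, inner CV and
  t-SNE; two runs of `cross_validate` produce byte-identical reports.
- BVH motion values are written with 10 significant digits so a write/read
  cycle reproduces world positions to ~1e−8 file units.

## Known limitations

- Cross-validation requires equal codebook sizes across records (records
  shorter than `N_c` frames are only supported outside CV).
- The codebook is per-record; a dataset-global codebook mode is not
  implemented.
- Only BVH I/O is supported (no C3D/ASF-AMC), and parsing assumes position
  channels precede rotation channels within a joint, as BVH files in
  practice do.
- Exact permutation equivariance of the codebook holds only when the
  clustering is stable; with near-degenerate affinity spectra the seeded
  k-means tie-breaking is order-dependent.
- t-SNE coordinates, even MDS-initialized, remain a nonlinear stochastic
  summary; the correlation analysis should be read as exploratory, not as
  an effect-size estimate.
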