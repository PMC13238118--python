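# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind `scgale`, in the spirit of a package methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

The central object is a cells × features non-negative count matrix with
per-cell type labels and optional QC columns (mitochondrial read count,
TSS enrichment, nucleosome signal). Quality control is quantile-based so
the same rigidity applies to any dataset: cells whose non-zero-feature
count (and, for gene expression, mitochondrial read count) falls *strictly*
outside the [5%, 95%] quantiles of the per-cell distribution are removed,
as are features whose detection count (cells with a non-zero value) falls
strictly outside the same band of the per-feature distribution. Quantiles
use linear interpolation between order statistics. Two consequences are
deliberate: a degenerate all-equal distribution removes nothing, and QC is
*not* exactly idempotent on all-distinct distributions (re-estimated bands
sit strictly inside the old ones), converging only where the band interior
is tied. Cells detecting zero features are always removed. ATAC-style
matrices additionally drop cells with TSS enrichment < 2 or nucleosome
signal > 2 when those columns are present; absent columns skip the rule and
are recorded in the QC report.

Counts are then library-size normalised (default target: the median
per-cell total), reduced to highly variable features when requested (top
10% by variance for gene expression; variance strictly above the 80%
quantile, capped at 30 000, for peaks/windows; variance computed on
normalised, pre-log values; ties broken by ascending feature index), and
log(1+x)-transformed. No imputation is performed.

The Wilcoxon differential baseline ranks features per class (one vs rest)
by the standardised rank-sum statistic with midranks and tie-corrected
variance; p-values are exact (full enumeration) for comparisons of ≤ 20
cells and normal approximations otherwise. The test suite cross-checks the
statistics against scanpy's implementation (agreement ≲ 1e-5) and the
exact p-values against independent enumeration.

## Geometry target

The autoencoder's regularisation target Ξ is a diffusion-potential
embedding: pairwise Euclidean distances; adaptive-bandwidth α-decay kernel
K_ij = ½[exp(−(d_ij/σ_i)^α) + exp(−(d_ij/σ_j)^α)] with σ_i the distance to
the 5th neighbour (floored at the smallest positive distance when rows
duplicate) and α = 40; row-normalisation to a diffusion operator P; the
diffusion time t chosen at the knee (maximum chord distance) of the von
Neumann entropy of the spectrum over t ∈ [1, 100]; potentials
U = −log(Pᵗ + ε) with ε the float64 machine epsilon; metric MDS of the
potential distances to p = ⌈∛F⌉ dimensions, initialised at the classical
MDS solution and refined by SMACOF majorisation (stress is therefore
non-increasing). The embedding is computed on the processed matrix
directly, not on a PCA compression; this is configurable but the default
keeps the contract simple. Powers of P are computed through the
eigendecomposition of the symmetric conjugate D^{1/2} P D^{-1/2}, which is
exact and O(n³) once.

## Autoencoders

All nonlinear models share one architecture derived from the feature count
d: input d → hidden ⌈√d⌉ → latent ⌈∛d⌉ and the mirrored decoder, LeakyReLU
(slope 0.2) on hidden layers, linear latent and output (inputs are
log-scale reals). Training is full-batch Adam, an 85/15 seeded validation
split (stratified by label when labels exist), at most 300 epochs with
early stopping after 30 epochs without validation improvement, and
restoration of the best-validation weights.

The geometry-regularised loss is
L = MSE(X, f⁻¹(f(X))) + λ · (1/N) Σ ‖ξᵢ − f(xᵢ)‖². The geometric sum is
averaged over cells so one λ transfers across dataset sizes; the default is
λ = 0.1. Ξ is rescaled to [−1, 1] before entering the loss — the raw MDS
potential coordinates are on an arbitrary scale (tens to hundreds) that
would otherwise let the geometric term dominate the reconstruction term for
any fixed λ; the reference implementation of geometry-regularised
autoencoders makes the same normalisation. With λ = 0 the objective —
and, under equal seeds, the entire training trajectory — coincides with the
vanilla AE, which the acceptance suite asserts to 1e-6.

The VAE baseline adds β(t)·KL(q‖N(0,I)) with β annealed linearly from 0 to
1 over the first half of the epoch budget; the PCA baseline uses exact SVD
scores with the inverse transform as decoder.

The default learning rate is 5e-3. Full-batch gradients are noiseless, and
at desk scale the conventional mini-batch value of 1e-3 leaves every model
at the 300-epoch cap with the validation loss still falling (the geometric
residual stays ~4× higher); 5e-3 lets training reach its early-stopping
optimum inside the budget for all embedders equally.

Corruption for the denoising benchmark zeroes ⌈fraction·F⌉ whole feature
columns, sampled uniformly per seed, matching the experiment it emulates.

## Cell graph and classifiers

The cell graph links each cell to its k = 15 nearest latent-space
neighbours (exact brute-force search at these scales, stable argsort so
distance ties resolve by ascending index) and symmetrises by union, which
cannot isolate nodes. Edges are unweighted: edge relevance is learned by
the attention mechanism, not imposed by distances.

The GAT has two layers. Layer 1 uses 4 attention heads of width
⌈∛F⌉ each, concatenated, followed by LeakyReLU; layer 2 is a single head
producing the class logits, softmax-normalised. Attention scores follow
aᵀ LeakyReLU(Θ_s xᵢ + Θ_t xⱼ) with the softmax taken over N(i) ∪ {i}
(self-loops added explicitly), so attention rows are exact probability
distributions — the trainer records the maximal row-sum deviation each
epoch and the acceptance suite asserts it below 1e-6. Dropout 0.3 is
applied to inputs and attention coefficients during training only. The GCN
baseline replaces attention with the symmetric-normalised adjacency
convolution. Node splits are stratified 70/10/20 (train/validation/test),
cross-entropy is minimised on training nodes with Adam (lr 5e-3, weight
decay 5e-4), early stopping mirrors the autoencoders, and all reported
classification metrics (accuracy and macro-averaged precision/recall/F1)
are computed on test nodes only.

## Explainer

For a node v the explainer freezes the trained classifier and learns a
feature mask (length F, shared across the node's two-hop computation
subgraph) and one mask per undirected subgraph edge, both parameterised
through a logistic squashing of free parameters initialised near 1
(logit 3 plus N(0, 0.1) noise). The masked features multiply X elementwise;
the edge gates multiply the post-softmax attention (or the normalised
adjacency weights for a GCN) on both directed copies of each edge, with
self-loops fixed open. The mutual-information objective is optimised
through its standard surrogate: cross-entropy between the model's original
predicted class at v and its prediction under the masked inputs, plus size
penalties (mean mask × weight) and elementwise Bernoulli entropy penalties.
Default weights are feature-size 1.0, feature-entropy 0.1, edge-size 0.005,
edge-entropy 1.0 — the canonical calibration of the mask-explainer family.
This balance matters: if the feature-size weight is much smaller than the
feature-entropy weight, the entropy term (whose gradient at mask ≈ 0.95
points *towards* 1) saturates every mask and the explanation carries no
signal; with the defaults above the planted-marker fixtures are recovered
at 95–100% in the top-50.

Class explanations average the feature masks of the class's nodes (a seeded
subsample, default cap 500, configurable to ∞; subsampling is recorded and
unbiased for the mean), rank features by mean mask descending with ties
broken by ascending index, and report the top-n set (default n = 50). Edge
masks sharpen fidelity but do not enter the class ranking. The importance
decay curve is the absolute first difference of importance along the rank.

## Evaluation metrics

Reconstruction: MSE over all entries; Spearman over the flattened entry
pairs (midranks; per-feature averaging available behind a flag); MSE1obs /
MSE1imp restrict the MSE to the ⌈1%·F⌉ most-covered features with coverage
counted on the observed or the reconstructed matrix; the NB loss is the
mean negative log-likelihood under mean μ and inverse-dispersion θ
(Var = μ + μ²/θ; θ estimated by method of moments when not supplied; μ
floored at 1e-8).

Graph homogeneity: per cell, the number of distinct label values among its
k *directed* nearest neighbours (self excluded, exactly k each, so the
divisor is exact), divided by k·C; homogeneity is one minus the mean.

Explanation quality: specificity is one minus the mean cross-class overlap
|A∩B|/n of top-n sets over unordered class pairs; stability is the mean
over classes of the mean pairwise overlap across repeated runs;
explainer-vs-differential similarity is |XAIF∩DAF|/n (Jaccard behind a
flag). The signal-to-noise ratio of a feature for a class is
(mean inside − mean outside)/(sd inside + sd outside + 1e-8) — there is no
single canonical definition of this ratio in the field, so the two-group
standardised difference is the documented, configurable choice. Technical-bias overlap compares a
feature set against the equally sized top set by total expression or by
coverage.

## Synthetic study conditions

`generate_counts` plants C cell types (largest-remainder allocation of the
type proportions, then a seeded shuffle) and gives each type a disjoint
block of marker features whose NB mean is `base_mean · 2^effect_log2fc` in
type and `base_mean` outside; every entry is then zeroed independently with
probability `dropout_p`. The NB parameterisation (mean μ, inverse-dispersion
θ) is shared with the NB loss. Defaults — 2000 cells, 500 features, C = 4,
20 markers per type, effect 2 (4-fold), base mean 2, θ = 2, dropout 0.3 —
define the statistical structure used throughout the tests; the acceptance
checks run the same structure at 600 cells (300–500 features) to keep the
default suite in CPU minutes. `generate_trajectory_counts` places cells on
a uniform pseudotime per branch and gives each branch a feature block whose
mean rises sigmoidally (steepness 10 around the midpoint) from the base to
the full fold-change; labels discretise branch × pseudotime bin. Under the
default noise a single trajectory feature correlates ≈ 0.2 with pseudotime
(the NB variance at the high end of the sigmoid is ~40 against a signal
range of 6) — tests assert the oracle-computed band, not an optimistic one.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, fragment-level ATAC structure, and — importantly — correlated feature
programmes beyond the planted blocks. Features are conditionally
independent given the type. Passing tests therefore demonstrate the
machinery (losses, orderings, recovery of planted signal), not performance
on real correlated data.

One documented consequence: the denoising ordering observed on real data
(geometry-regularised reconstruction beating the vanilla AE at every
corruption level) does **not** reproduce under these synthetic conditions.
Whole-column corruption trains both models to output zero on dropped
columns, conditional feature independence leaves the geometric prior no
extra information about the surviving ones, and with validation early
stopping the unregularised AE never reaches the overfitting regime where a
regulariser pays for itself; across λ spanning 0.1–100, learning rates
1e-3–1e-2, dropout and weight-decay variations, and problem sizes up to
2000×500, the AE's mean reconstruction MSE stays ~1–2% below the GRAE's.
The corresponding acceptance check is kept faithful to the claimed ordering
and fails honestly on this fixture family.

## Known limitations

* All dense-matrix algorithms (distances, eigendecompositions, full-batch
  training) are O(n²)–O(n³) in cells; the intended scale is ≤ ~5000 cells.
* The explainer runs one optimisation per node; class explanations rely on
  subsampling for large classes.
* TSS enrichment and nucleosome signals are accepted as input columns only;
  they are never computed from fragments.
* The random-search tuner for the autoencoder and classifier is opt-in;
  all defaults are fixed and seeded so no test depends on tuning.
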