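# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `hccfusion`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Radiomics feature registry

Each VOI yields exactly 100 features: 18 first-order, 14 shape, 68
texture (GLCM 22, GLRLM 16, GLSZM 16, GLDM 14). Conventions:

- **Resampling** to 1 × 1 × 1 mm (trilinear for intensities,
  nearest-neighbour for masks) precedes everything; physical distances
  always use the voxel spacing.
- **Discretization** uses a fixed bin width (default 25 intensity units)
  anchored at the in-mask minimum: `level = floor((I − min)/w) + 1`.
  Anchoring at the minimum makes all texture features invariant to adding
  a constant to the image, which the tests verify.
- **Peritumoral shell**: voxels with Euclidean distance to the tumor in
  (0, r] mm (default r = 10), minus the tumor and an optional exclusion
  mask (non-liver tissue, vessels, air). Computed with an exact distance
  transform, so shells nest monotonically in r.
- **Surface area by voxel-face counting**, not a marching-cubes mesh.
  This is deterministic and exactly testable (a unit voxel has surface
  6 mm², surface-to-volume ratio 6 mm⁻¹) but runs systematically larger
  than mesh-based areas; Sphericity and SurfaceVolumeRatio are therefore
  comparable within this registry only. MeshVolume consequently equals
  VoxelVolume.
- **GLCM**: distance 1, symmetric accumulation over the 13 unique 3D
  directions, features evaluated per direction and then averaged
  (feature-then-average). GLRLM likewise. GLSZM zones and GLDM
  dependences use 26-connectivity; GLDM requires exact level equality
  (α = 0). These are the common defaults; they are stated here because
  the upstream description names a tool without settings.
- **Degenerate inputs**: constant regions return the limit value of each
  feature (skewness/kurtosis 0, GLCM Correlation 1, Idn/Idmn 1, …) and
  the event is logged; a single-voxel VOI has no co-occurring pairs and
  falls back to the degenerate single-cell GLCM.

Every texture feature is checked against a brute-force oracle (explicit
enumeration of voxel pairs, runs, zones and dependences with naive
formula transcription) to 1e-10 on 50 random 5 × 5 × 3 arrays.

## Fusion subtyping

Affinities use the scaled-exponential kernel with locally adaptive
bandwidth ε_ij = (mean k-NN distance of i + mean k-NN distance of j +
d(i,j))/3 and μ = 0.5. The neighbourhood size defaults to
k = min(20, ⌊n/3⌋): the common default k = 20 is degenerate at n = 30.
SNF runs T = 20 message-passing iterations; each view's status matrix is
renormalized (half the probability mass on the diagonal) and symmetrized
per iteration, and the fused output is the symmetrized, row-normalized
average. With a single view there is nothing to fuse and the normalized
input is returned; `iterate_single=True` instead applies `P ← S P Sᵀ`
for the same T iterations, which exactly reproduces the trajectory of
m identical fused copies (the two behaviors differ because fusion
diffuses the network; both are tested).

Spectral clustering embeds patients in the k smallest eigenvectors of
the symmetric normalized Laplacian, row-normalizes the embedding and
runs k-means with 50 restarts under a fixed seed.

**Model selection.** Consensus clustering re-runs the entire
affinity → fuse → cluster pipeline on each of 1000 subsamples of 80% of
the patients (resampling only the final clustering would understate the
pipeline's variability). consensus(i,j) = co-cluster count / co-sample
count; never co-sampled pairs are flagged and excluded from the CDF.
The cluster number minimizes the proportion of ambiguous clustering,
PAC(k) = CDF(0.9) − CDF(0.1), with ties within 0.01 resolved toward the
smallest k. A delta-area rule on the CDF ("largest k with > 10% relative
area gain") was considered and rejected: splitting a clean cluster at
k+1 always adds substantial CDF area, so the rule is structurally biased
toward large k — on clean planted two-subtype cohorts it selects k = 4
while PAC is exactly 0 at k = 2 and ≈ 0.45 elsewhere. The per-k CDF
areas and relative gains are still reported as diagnostics.

For k = 2, FIFS1 is anchored to the better-prognosis arm by restricted
mean survival time (area under the Kaplan–Meier curve up to the last
follow-up), which is invariant to label permutation and well defined
even when both arms reach S = 0.

The silhouette score is computed on the dissimilarity
d(i,j) = 1 − P̂(i,j)/max off-diagonal P̂ of the symmetrized fused network
(the raw-feature-space variant can be obtained by silhouette on feature
distances directly; the fused-similarity variant is the default because
the fused network is the object the clustering actually sees).

## Survival

Kaplan–Meier, log-rank and Cox proportional hazards are delegated to
lifelines behind a typed façade. Ties use the Efron correction — the
only correction the backing fitter implements, hence no Breslow switch —
and confidence intervals are Wald, exp(coef ± 1.96 SE), matching the
"HR (95% CI)" presentation convention. Non-convergent or separated fits
raise instead of returning silent output. The identity between the
two-group log-rank statistic and the Cox score test at β = 0 is used as
an independent oracle in the tests.

## Expression statistics

- **Normalization**: median-of-ratios size factors over genes nonzero in
  every sample.
- **Differential expression**: Welch t-test on log2(normalized + 1) with
  BH adjustment; significant ⇔ |log2FC| > 1 and adjusted p < 0.05. This
  deliberately replaces shrinkage-based negative-binomial estimators: the
  analysis' substance is the thresholds and the downstream cascade, and
  the simple test is desk-verifiable. It is *not* numerically identical
  to NB shrinkage methods; with 15 samples per arm its operating
  characteristics (type-I ≤ 5%, sensitivity ≥ 90% at 4-fold changes and
  dispersion 0.1) are verified by simulation.
- **Gene-set scoring**: the rank-based single-sample running-sum
  statistic with weight 0.25 (weighted in-set ECDF minus out-set ECDF,
  summed over the ranked list, globally max−min rescaled). It depends
  only on within-sample ranks, hence is invariant to monotone transforms.
  Immune/stromal infiltration scores are the same scorer applied to
  user-supplied immune/stromal gene sets — no separate code path.
- **Over-representation**: one-sided hypergeometric upper tail, BH across
  sets. The DE reference class is fixed to FIFS1 and recorded in the
  result metadata.

## Co-expression modules

Signed adjacency `((1 + cor)/2)^β` with β = 8 (fixed; a scale-free-fit
scan is out of scope), smoothed into the topological overlap measure.
Modules are branches of average-linkage clustering on 1 − TOM under a
static cut with a minimum size of 30 genes; smaller branches go to
"grey". The static cut replaces dynamic-hybrid tree cutting for
determinism; exact module boundaries are not the claim — module–feature
correlations are. The cut height defaults to 0.98: at β = 8 the TOM
distances of uncorrelated genes concentrate near 0.99, so the
superficially natural 0.995 merges the whole transcriptome into one
cluster, while 0.98 separates planted modules (within-module TOM
distance ≈ 0.6) from noise. A median-absolute-deviation pre-filter to
the 5000 most variable genes is applied by default. Eigengenes are
unit-variance first principal components, sign-oriented so the mean
correlation with member genes is positive.

## PRF cascade and association network

Stage 1 keeps features with a two-sample t-test p < 0.05 between
subtypes; stage 2 keeps those with univariate Cox p < 0.05 on the
z-scored feature. Under permuted survival the stage-2 pass rate among
stage-1 survivors is ≈ 5%, which the acceptance script measures.
PRF-related modules must pass three filters: eigengene–subtype
correlation p < 0.05, eigengene Cox p < 0.05, and ≥ 1 PRF with
eigengene–feature correlation p < 0.05. Pathway–feature pairs use
Pearson correlation with a single BH correction across the full
pathway × PRF grid (q < 0.05) — controlling the FDR the network
visualization implies — and the association network keeps the top five
pairs per PRF by |r| (ties by pathway name). The top correlated member
gene per PRF (max |r| with p < 0.05) is reported with its pathway and
module. In the self-contained pipeline run the "pathways" of a module
are the module's own gene set; user-supplied GMT collections refine this
to true pathway granularity.

## Subtype classifier

Nearest shrunken centroids in the canonical parameterization:
`d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s₀))` with `m_k = sqrt(1/n_k − 1/n)`,
pooled within-class SD s_i, fudge s₀ = median(s_i), soft-thresholding
`d'_ik = sign(d)(|d| − Δ)₊` and prediction by the standardized squared
distance minus 2·log(prior). Expression is not pre-standardized; the
(s_i + s₀) scaling standardizes implicitly as in the canonical method.
The threshold grid is 30 even values on [0, max|d_ik|]; Δ is chosen by
stratified 10-fold cross-validation as the largest threshold attaining
the minimal error (fewest genes at the lowest error). Discriminant ties
break to the lexicographically first class and are flagged. Priors are
empirical training frequencies.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, nothing
more:

- **Features**: i.i.d. standard normal per column; a fraction (default
  30%) of the texture columns receives a subtype-2 mean shift of ±1.5 SD
  with random sign. Cross-view correlation arises only through the shared
  latent subtype — the simplest structure under which fusion helps.
- **Subtypes**: proportions default to 16/30 vs 14/30, the discovery
  split the analysis design assumes.
- **Counts**: negative binomial (gamma–Poisson) with dispersion 0.1 and a
  planted "immune" module (100 genes, log2 effect +2 in subtype 1) and
  "cell_cycle" module (80 genes, +2 in subtype 2), mirroring the
  inflammation-versus-proliferation contrast the subtypes represent.
  Per-gene baseline abundances come from a catalog RNG with its own fixed
  seed so that independently generated cohorts (discovery vs validation)
  share gene baselines, as real paired cohorts measured on the same
  transcriptome do; re-drawing baselines per cohort would inject a
  log-normal pseudo batch effect of ≈ 1.4 log2 units per gene and is not
  what external validation assumes.
- **Survival**: exponential with subtype-2 log-hazard ln(1/0.146) ≈ 1.92
  (the hazard-ratio magnitude reported for the discovery cohort), median
  baseline survival 900 days, and uniform administrative censoring whose
  horizon is solved numerically for the requested censoring rate
  (default 30%). Uniform administrative censoring keeps the KM/Cox
  oracles closed-form.
- **Clinical**: log-normal AFP-like marker elevated in subtype 2 and an
  ordinal grade shifted toward higher grades in subtype 2.
- **Volumes** (optional): ellipsoidal lesions on a liver-like background;
  subtype-1 lesions are low-intensity and heterogeneous (high GLCM
  contrast), subtype-2 high-intensity with a smooth gradient (low
  contrast); the venous phase adds a +20 intensity offset.

The separating effect sizes are calibration choices of this package —
the source analysis never quantifies how strongly its subtypes separate.
What passing tests show is therefore that the pipeline recovers structure
of the stated form at these effect sizes, not that it would on any given
real cohort; real CE-CT adds scanner effects, segmentation variability
and correlated features that the generator deliberately omits.

## Problem sizes

Default desk-scale conditions: n = 30 discovery patients, 150 validation
patients, 2000 genes, 1000 consensus resamples, 20 recovery seeds, 60
Cox-coverage replicates at n = 2000, 10 classifier seeds. These sizes
make every stage's statistical claim measurable in minutes on one CPU
while keeping the estimates' standard errors small relative to the
margins asserted.

## Known limitations

- Face-counted surface areas and voxel-based volumes diverge from
  mesh-based tools; shape features are internally consistent only.
- The DE test and the rank-based scorer are documented substitutions,
  not numerical replicas of NB-shrinkage DE or kernel-density GSVA.
- Static-cut module detection can absorb correlated noise genes into
  planted modules at n = 30 samples; downstream filters (DE overlap,
  module filters) tolerate this, but module boundaries should not be
  over-interpreted.
- The delta-area diagnostics are reported but not used for k selection
  (see above); PAC is the selection rule.
- No scanner batch-effect model, DICOM handling, wavelet/filtered
  feature variants, or competing-risks survival.
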