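# hccfusion

Multi-view CE-CT radiomics fusion subtyping and radiogenomics association
analysis for hepatocellular carcinoma (HCC), rebuilt as a tested, desk-scale
Python pipeline driven by a synthetic-cohort generator with known ground
truth.

## Who this is for

Researchers who want to study, stress-test or extend a radiogenomics
workflow of the following shape without access to protected imaging and
expression cohorts: contrast-enhanced CT lesions are described by
quantitative imaging features from several complementary views, patients
are clustered by fusing per-view similarity networks, and the resulting
imaging subtypes are linked to survival, differential gene expression,
co-expression modules and an expression-based classifier that transfers
the subtypes to imaging-free cohorts.

## What the pipeline computes

1. **Multi-view feature extraction.** For each lesion, four volumes of
   interest (VOIs) are analysed: tumor and 10 mm peritumoral shell, in the
   arterial and portal venous phase. Images are resampled to 1 mm
   isotropic voxels and discretized with a fixed bin width of 25. Each VOI
   yields 100 features: 18 first-order intensity statistics, 14 3D shape
   descriptors, and 68 texture features from the gray-level co-occurrence
   (GLCM, 22), run-length (GLRLM, 16), size-zone (GLSZM, 16) and
   dependence (GLDM, 14) matrices — 400 z-scored columns per patient.
2. **Fused subtyping (FIFS).** Per view, a patient similarity network is
   built with the scaled-exponential kernel
   `W(i,j) = exp(-d²(i,j) / (μ ε_ij))`, the networks are merged by
   similarity network fusion (SNF) message passing
   `P_v ← S_v (Σ_{u≠v} P_u / (m-1)) S_vᵀ`, and the fused network is
   clustered spectrally. The number of subtypes is chosen by consensus
   clustering (1000 reps of 80% resampling of the whole pipeline),
   minimizing the proportion of ambiguous clustering across the per-k
   consensus CDFs. For two subtypes, FIFS1 denotes the better-prognosis
   arm.
3. **Prognostic radiomics features (PRFs).** A two-stage cascade: features
   that differ between subtypes (two-sample t-test, p < 0.05) and are
   prognostic in a univariate Cox model (p < 0.05), reported with hazard
   ratios and Wald 95% CIs.
4. **Expression analysis.** Median-of-ratios normalization; differential
   expression (Welch t on log2 normalized counts, significant when
   |log2FC| > 1 and BH-adjusted p < 0.05); signed co-expression networks
   (`a_ij = ((1 + cor)/2)^β`, β = 8) smoothed by topological overlap, with
   modules of at least 30 genes and first-principal-component eigengenes;
   rank-based single-sample gene-set scores (ssGSEA-style, weight 0.25).
5. **Radiogenomics association.** Modules linked to subtype, prognosis and
   at least one PRF are retained; pathway scores are Pearson-correlated
   with PRF eigenvalues (one BH correction across the grid, q < 0.05) and
   the top five pairs per PRF form a bipartite association network; the
   most correlated member gene per PRF is reported.
6. **Subtype classifier.** Candidate genes = differentially expressed
   genes ∩ PRF-related-module genes; a nearest shrunken centroid model
   (`d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s₀))`, soft-thresholded at Δ chosen
   by stratified 10-fold cross-validation) predicts subtypes for external
   expression-only cohorts, validated by Kaplan–Meier/log-rank separation
   and immune gene-set scores.

## Worked example

```python
from hccfusion import synthetic, fusion
from sklearn.metrics import adjusted_rand_score

cohort = synthetic.generate_cohort(synthetic.CohortConfig(n_patients=30, seed=42))
views = {v: cohort.features.zscore().view(v).to_numpy()
         for v in ("type1", "type2", "type3", "type4")}

result = fusion.consensus_select_k(views, n_reps=1000, fraction=0.8, seed=42)
fused = fusion.fuse_views(views)
labels = fusion.spectral_cluster(fused, result.chosen_k, seed=42)

print("chosen k:", result.chosen_k)
print("ARI vs planted subtypes:", adjusted_rand_score(cohort.subtype_labels, labels))
print("silhouette:", round(fusion.silhouette_from_similarity(fused, labels), 3))
```

prints

```
chosen k: 2
ARI vs planted subtypes: 1.0
silhouette: 0.296
```

i.e. consensus clustering selects two subtypes on the planted two-subtype
cohort, the fused network recovers the latent labels exactly, and the
fused-similarity silhouette quantifies cluster homogeneity.

The same analysis runs end to end from the command line:

```
hccfusion synth --n-patients 30 --seed 42 --out cohort/
hccfusion fifs --features cohort/features.csv --survival cohort/survival.csv \
    --reps 1000 --seed 42 --out fifs/
hccfusion run-all --seed 42 --out runs/demo
```

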