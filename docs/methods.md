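# Methods

## Scope and model

`netstrat` stratifies a genotyped cohort by the *location* of its variant
burden on a tissue-specific protein–protein interaction (PPI) network,
rather than by raw variant counts. The object being clustered is a
subjects × edges matrix of **edge conservation scores**

    burden(s, e=(g1,g2)) = (m_s(g1) + m_s(g2)) / (M(g1) + M(g2))
    score(s, e) = 1 − burden(s, e)

with m_s(g) the subject's carried selected variants in gene g and M(g) the
number of distinct selected variants of g carried by at least one cohort
subject. The score is cohort-relative by construction: M(g) uses
cohort-observed variants (per the documented worked example, m=(2,4) with
M=(4,6) → burden 0.6, score 0.4), not the full annotation list, so an
annotated variant nobody carries changes nothing. Carriage is binary per
variant (heterozygous and homozygous both count once); allele-dosage
counting is available behind `compute/VCF` ingestion but off by default.
Edges whose genes have no cohort-observed variants (zero denominator) score
1 for everyone and are flagged; constant columns can be dropped before
clustering since they carry no information.

**Feature-space definition.** Genes enter the scored subnetwork if at least
one of their *genotyped* selected variants is exonic-class
(`{exonic, missense, synonymous}` by default, configurable). Scoring then
uses *all* retained variants of surviving genes, including intronic ones —
intronic variants in retained genes demonstrably carry signal (they tag
haplotypes), and only the node filter is exonic-based. Variants annotated to
several genes count under every annotated gene (logged). Isolated nodes are
dropped: they contribute to no edge score.

## Affinity construction and clustering

Distances are squared Euclidean on the edge-score profiles, with no feature
standardization (scores already share the [0, 1] scale; a flag exists).
Affinities use the K-nearest-neighbour adaptive bandwidth
ε_ij = (mean_d(i,KNN) + mean_d(j,KNN) + d_ij)/3 with K ≈ n/10 by default.
Two kernel dialects are provided:

* `exp`: W_ij = exp(−d_ij/(μ·ε_ij)) — the original similarity-network-fusion
  (SNF) publication's kernel, and the form all kernel-level oracle tests
  target. It is exactly invariant to rescaling the features (ε scales with
  d).
* `density` (pipeline default): the Gaussian density N(d_ij; 0, μ·ε_ij).
  Its 1/(μ·ε) prefactor boosts affinities inside locally tight
  neighbourhoods, which measurably improves recovery of small, dense
  clusters — the regime a 5 %-of-cohort genetic subgroup lives in. This is
  also the convention of the widely used Python SNF implementation.

Multiple data views are merged by SNF cross-diffusion: per view, the
full-kernel matrix P (diagonal 1/2, off-diagonal W_ij/(2Σ_{k≠i}W_ik)) is
propagated through the view's row-normalized KNN kernel S as
P ← S·mean(other P)·Sᵀ for t = 20 iterations, renormalized and symmetrized
each step, then averaged. A single view (the only case the edge-score
pipeline exercises) returns the symmetrized full-kernel normalization
unchanged. Note that cross-diffusion is a *fixed point* for block-uniform
affinities but genuinely evolves generic inputs; identical views stay
identical to each other throughout.

Spectral clustering takes the k smallest eigenvectors of the symmetric
normalized Laplacian and rescales them by D^(−1/2) (diffusion-map /
random-walk coordinates) before seeded k-means with 100 restarts. The
degree rescaling was chosen over Ng–Jordan–Weiss row normalization because
it is markedly better at keeping a small tight cluster from being absorbed
into a large diffuse one; on block-diagonal affinities both are exact.

### Model selection

A (μ, k) grid (μ ∈ {0.2, …, 0.8} step 0.1; k ∈ 2..10; K fixed) is evaluated
and *ranked*; the caller chooses the working solution, and the pipeline
refuses to auto-pick when the top two scores are within 0.2 of each other
(an ambiguous ranking is a scientific decision, not a tie-break).

Two silhouette notions coexist, deliberately:

* **Affinity silhouette** (`similarity_silhouette`, reported per solution):
  a similarity-native per-sample silhouette with cohesion a_i = mean
  affinity to own cluster, separation b_i = largest mean affinity to another
  cluster, s_i = (a_i−b_i)/max(a_i,b_i). It is invariant to rescaling the
  affinity and reduces to 1 on ideal blocks. Max-shift
  (D′ = max(A)−A) and relative (1 − A/max(A)) dissimilarity conversions are
  available behind flags; the two conversions give identical silhouettes
  (they differ by a positive scale), and the off-diagonal maximum is used
  because the normalized diagonal (1/2) lives on a different scale.
* **Feature-distance silhouette** (ranks the grid, default): the standard
  silhouette evaluated on the shared squared-Euclidean feature distances.
  Silhouettes computed on each grid point's *own* affinity are not
  comparable across μ — a sharper kernel always inflates its own contrast,
  and in planted-data experiments it systematically ranked fragmented
  sharp-kernel partitions above correct ones. Scoring every candidate
  partition against the one μ-independent geometry removes that artifact;
  `SNFConfig(selection="affinity")` restores the affinity-based ranking.

## Genetic cluster profiling

Per-edge one-way ANOVA across clusters with Tukey's HSD on the significant
edges; significance at raw p < 0.05 by default (the 102-edge scan is small),
with a Benjamini–Hochberg flag that is recommended for larger edge sets.
Variants mapped to genes flanking significant edges become features of
one-vs-rest random forests, one per cluster, on a stratified 80/20 split.
Because cluster sizes are typically very unbalanced, each of the 500 trees
is grown on a **balanced bootstrap** (equal draws with replacement from the
positive cluster and the rest); importances are mean impurity importances,
and the held-out confusion matrix is reported alongside the top-10 ranking.
With √p features per split, a perfectly separating feature saturates near
importance 0.4 (it is simply absent from most root-split draws) while still
ranking first by an order of magnitude — importance magnitudes should be
read comparatively, not absolutely.

## Phenotype and imaging profiling

Cohort-description tables per diagnostic stratum (MCI, Dementia) report
n (%) for categorical variables with Pearson chi-square (no continuity
correction; small expected counts are warned about, as they genuinely occur
in few-subject clusters) and mean ± SD with ANOVA + Tukey for continuous
variables; missing values are deleted pairwise per variable.

ROI hypometabolism models consume a long table of (subject, ROI, SUVR,
time, sex, age, group) records — image processing upstream of ROI
aggregation is out of scope. Per ROI:

* baseline: OLS `suvr ~ cluster + sex + age` on time-0 records. With one
  observation per subject a random intercept is unidentifiable, so the
  baseline model is deliberately OLS rather than a mixed model.
* longitudinal: random-intercept linear mixed model
  `suvr ~ cluster*time + sex + age`; the cluster×time interaction tests for
  divergent metabolic trajectories. Non-convergent fits are retried with
  alternative optimizers and dropped (with a warning) if none succeeds.

P-values are BH-adjusted across ROIs *within* each cluster contrast
(matching one FDR family per analysis; pooling is behind a flag);
significant contrasts with coefficient ≤ −0.05 get the "most affected"
flag. ROIs with fewer than 10 observations are skipped. The AAL 116-region
label vocabulary ships with the package.

## Cognitive networks

Each cluster's ADAS-Cog network has the 13 items as nodes and mean
bootstrap partial correlations as weights: 250 repetitions, each drawing 10
subjects without replacement (both configurable; with-replacement behind a
flag). With 10 observations of 13 variables the sample covariance is
singular — the central undocumented estimation choice here — so the
estimator shrinks the correlation matrix toward the identity with the
analytic Ledoit–Wolf intensity before inversion; a pseudo-inverse
alternative sits behind a flag. Partial correlations are
ρ_ij = −Θ_ij/√(Θ_ii·Θ_jj) from the (regularized) precision Θ.

Global metrics (density, average degree, average unweighted clustering
coefficient, diameter = max finite eccentricity on disconnected graphs) are
computed per repetition on the graph binarized at |w| ≥ τ (τ = 0.05
default, since partial correlations below that are noise-level at n = 10),
giving bootstrap distributions that are compared across clusters by
ANOVA + Tukey. **Caveat:** bootstrap replicates are pseudo-replicates, not
independent samples; treating their distributions as ANOVA groups (as the
protocol specifies) makes these p-values descriptive rather than
calibrated. This is reproduced as specified and not silently "fixed".
Degree centrality per node is averaged over repetitions and normalized by
(n_items − 1).

## Synthetic cohort generator

The generator emulates the six pipeline inputs with planted truth; all
generators are pure functions of (config, seed).

* PPI layer: connected random graph grown from a spanning tree with
  preferential attachment to designated hub genes (one per cluster by
  default), surplus edges half hub-anchored — hubs end well above median
  degree, mirroring high-centrality disease genes. Default scale 66 nodes /
  102 edges.
* Genotypes: default 728 subjects split 0.32/0.63/0.05 across three
  clusters. Each cluster's signature is a hub plus its strongest
  neighbours (5 genes at default scale, disjoint across clusters, 3
  variants per gene); members carry signature variants with probability 0.6
  versus 0.05 background, independently per variant. Each gene's first
  variant is missense (so genes survive exonic induction); signature
  variants carry cluster-specific disease CUIs from a ten-code
  neurodegeneration panel.
* Phenotypes: diagnosis, sex, APOE genotypes and biomarkers at
  cohort-typical frequencies and scales; per-cluster mean shifts in SD
  units are planted via config (default: tau markers +1 SD in the first
  cluster, age +1 SD in the third, mirroring the motivating trends).
* ROI SUVR: per (cluster, designated ROI), a −0.05 baseline offset and
  −0.02/year cluster×time slope on top of a subject random intercept
  (σ = 0.05) and noise (σ = 0.05), visits at 0/1/2 years, plus controls.
* ADAS-Cog: a latent Gaussian with a domain-block precision (within-domain
  partial correlation 0.2 — it must stay below 1/4 for positive
  definiteness given the 5-item language domain), discretized to each
  item's declared range by Gaussian-quantile binning.

`SimulationConfig.small()` (120 subjects, 20 genes, 30 edges, 3 signature
genes, 6 ROIs) is the CI-speed fixture; tests and the acceptance checks run
at this scale except the cohort-scale recovery checks, which use the full
default configuration (it runs in about a second per grid point).

**What the generator does not emulate:** linkage disequilibrium (real
signature variants are carried *together* on haplotypes, making real
clusters tighter than independent-Bernoulli ones), allele-frequency
spectra, population structure, missing phenotype patterns, and
measurement-batch effects. Passing recovery tests therefore demonstrate
correctness of the machinery under honest noise, not clinical performance.
A consequence worth knowing: at the 120-subject fixture scale the 5 %
cluster has 6 members and sits at the edge of spectral resolution with
K = 12 — recovery there averages ARI ≈ 0.92 with occasional ≈ 0.8 seeds,
whereas at the default 728-subject scale (38-member small cluster, K = 70)
recovery is ARI ≥ 0.99 across the entire μ grid.

## Numerical and policy choices

* Seeds: every stochastic step (generators, k-means, bootstraps, splits)
  takes an explicit seed; the pipeline refuses unseeded runs and writes a
  manifest (input hashes, versions, seed, chosen solution) sufficient to
  reproduce a run.
* Ties in grid ranking break toward smaller k.
* ε = 0 bandwidths fall back to machine epsilon with a warning; degenerate
  grid points are skipped with a warning and only an all-degenerate grid is
  an error.
* Zero-variance edge columns in the ANOVA scan are marked non-significant
  with NaN statistics rather than erroring.
* Bootstrap draws hitting a zero-variance item are redrawn (bounded); the
  shrinkage estimator handles near-singularity otherwise.

## Known limitations

* The edge score weighs all variants equally; pathogenicity weighting
  (e.g. CADD) is explicitly out of scope.
* The affinity-based silhouette should not be compared across kernel
  bandwidths; use the feature-distance ranking (default) for model
  selection and read affinity silhouettes within a fixed μ.
* Mixed-model standard errors are mildly anticonservative when latent slope
  heterogeneity exists within groups (random-intercept-only specification).
* The cognitive-network cluster comparison inherits bootstrap
  pseudo-replication (see above).
* Chi-square p-values in few-subject strata rest on expected counts well
  below 5 and are approximate; the tables warn when this happens.
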