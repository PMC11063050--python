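# netstrat

Genetics-driven patient stratification on tissue-specific protein–protein
interaction (PPI) networks.

Complex neurodegenerative diseases such as Alzheimer's disease are
genetically heterogeneous: patients with indistinguishable clinical
presentations can carry variant burdens in entirely different parts of the
brain interactome. `netstrat` implements a stratification pipeline for this
setting, aimed at researchers working with cohort genotype data (e.g. a WGS
cohort with curated variant–disease associations), a tissue-specific PPI
layer, and downstream phenotype tables:

1. **Network assembly** — filter variant–disease associations to a disease
   panel (UMLS CUI codes), map retained variants onto genes present in the
   cohort genotypes, and induce the PPI subnetwork on genes carrying at
   least one exonic-class variant.
2. **Edge conservation scoring** — for each subject *s* and each edge
   (g₁, g₂) of the subnetwork, compute

   ```
   burden(s, e) = (m_s(g1) + m_s(g2)) / (M(g1) + M(g2))
   score(s, e)  = 1 − burden(s, e)
   ```

   where m_s(g) is the number of selected variants the subject carries in
   gene g and M(g) the number of distinct selected variants of g observed in
   the whole cohort. A score of 1 is a fully conserved interaction, 0 a
   fully affected one. Example: m = (2, 4) against M = (4, 6) gives burden
   (2+4)/(4+6) = 0.6 and score 0.4.
3. **Similarity-network clustering** — squared-Euclidean distances between
   subjects' edge-score profiles become affinities through a scaled
   exponential kernel with K-nearest-neighbour adaptive bandwidth
   (W_ij = exp(−d_ij / (μ·ε_ij)); a density-adaptive Gaussian variant is the
   pipeline default), optionally fused across data views by SNF
   cross-diffusion, then spectrally clustered. A (μ, k) grid is ranked by
   silhouette and reported; the analyst chooses the working solution.
4. **Cluster phenotyping** — ANOVA + Tukey HSD edge scans with one-vs-rest
   balanced random forests ranking the variants that drive each cluster;
   chi-square / ANOVA demographic and biomarker tables per diagnostic
   stratum; per-ROI baseline (OLS) and longitudinal (random-intercept mixed
   model) SUVR contrasts against controls with Benjamini–Hochberg FDR; and
   bootstrap partial-correlation networks over the 13 ADAS-Cog items with
   graph-topology comparisons.

A synthetic-cohort module generates all six pipeline inputs with planted
ground truth (cluster labels, signature genes, ROI coefficients, subscore
precision matrix), so the full pipeline is testable without access-controlled
clinical data.

## Worked example

```python
import numpy as np
import netstrat as ns
from netstrat.synthetic_cohort import NEURODEGENERATION_CUIS

# synthetic 120-subject cohort with three planted genetic clusters
cfg = ns.SimulationConfig.small(seed=1)
bundle = ns.generate_all(cfg)

selected = ns.filter_vda_by_disease(bundle["annotations"],
                                    set(NEURODEGENERATION_CUIS))
gene_map = ns.build_variant_gene_map(selected, bundle["genotypes"])
subnet = ns.induce_brain_subnetwork(bundle["ppi"], gene_map, selected)
scores = ns.build_edge_score_matrix(bundle["genotypes"], subnet, gene_map)

sols = ns.model_selection_grid(scores, ns.SNFConfig(seed=42))
for s in ns.best_per_cluster_count(sols)[:3]:
    print(f"k={s.n_clusters}  mu={s.mu:.1f}  silhouette={s.rank_value:.3f}")
```

prints

```
subnetwork: 20 nodes, 30 edges
edge scores: 120 subjects x 30 edges
k=2  mu=0.3  silhouette=0.681
k=3  mu=0.6  silhouette=0.582
k=4  mu=0.4  silhouette=0.498
```

The two-cluster solution scores best, with three clusters a close second —
the three-cluster solution splits the larger group in two and recovers the
planted structure (cluster sizes 39/75/6, adjusted Rand index 0.968 against
the generating labels). Choosing the k = 3 solution and profiling it
(`anova_tukey_edge_scan`, `rf_one_vs_rest_importance`,
`summarize_cluster_phenotypes`, `fit_roi_model_*`,
`bootstrap_partial_correlations`) yields the cluster-defining edges, the
variants driving them, and the demographic, metabolic and cognitive
signature of each cluster.

The same flow is available from the shell:

```
netstrat simulate --seed 1 --out fixtures/
netstrat score --vda fixtures/vda.tsv --ppi fixtures/ppi.tsv \
               --genotypes fixtures/genotypes.tsv --out scores.tsv
netstrat cluster --scores scores.tsv --mu-grid 0.2:0.8:0.1 \
                 --k-range 2:10:1 --seed 42 --out solutions.json
netstrat run-all --config run.yaml
```

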