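# gbmspatial

Spatial single-cell analysis of matched primary/recurrent glioblastoma
tissue from multiplexed imaging and in-situ transcriptomics — as a tested,
reusable Python library.

Glioblastoma mixes genetically distinct tumor subclones (marked by *CDK4*,
*EGFR*, and *PDGFRA* amplifications and the TERT-promoter hotspot mutation)
with hypoxic, vascular, and immune microenvironments inside one tissue
section. This package implements the tabular half of an imaging study of
that interplay, for analysts who already have segmentation output (nuclear
centroids, FISH/STAR-FISH spot counts, marker positivity) or targeted-panel
spatial transcriptomics, and want the downstream statistics:

* **Cell classification** — deterministic genotype calls (a gene is
  amplified at ≥ 6 spots, nuclei at ≥ 50 spots of any gene are excluded as
  overlaps), TERTp mutation calls (any STAR-FISH signal), and phenotype
  assignment with precedence *tumor ∧ CD31 → EC-mimicry tumor; tumor;
  CD45RO → immune; CD31 → endothelial; else unclassified*, with nuclear
  HIF1α as an orthogonal hypoxia modifier.
* **Diversity and association statistics** — per-FOV frequency tables,
  Shannon index H = −Σᵢ pᵢ ln pᵢ, co-amplification odds ratios with
  Haldane–Anscombe correction, Pearson frequency correlations, paired
  Wilcoxon tests, Fisher contingency between FOV clusterings.
* **A quadrat species-distribution model (SDM)** — each FOV is tiled into
  199-px quadrats; a funnel network (12 → 36 ×10 → 24 → 12 → 3, batch norm,
  leaky-ReLU, linearly decaying dropout) predicts the ECM reflectance
  texture (string-like / spotty / mossy) from the quadrat's 12-category
  cell composition. Training uses SMOTE balancing, the class-balanced focal
  loss L = ((1−β)/(1−β^{n_y})) (1−p_y)^γ (−log p_y) with AdamW, 11
  mini-batches per epoch, and early stopping when validation loss diverges
  from a still-decreasing training loss. Replicated fits are interrogated
  with Integrated Gradients,
  IGᵢ = (xᵢ−x′ᵢ)·(1/m)Σₜ ∂F_c/∂xᵢ|_{x′+(t/m)(x−x′)},
  and per cell type the mean non-zero attribution over correctly classified
  quadrats is weighted by its informative frequency.
* **Niche analysis** — filter (≥ 5 detected features/cell), library+log
  normalisation, PCA → SNN → Leiden cell typing, then k-means over each
  cell's k = 30 nearest-neighbour type composition to call spatial niches.
* **Proximity enrichment** — Delaunay network with a maximum edge length;
  observed vs label-reshuffled expected type-pair adjacency,
  log2((obs+1)/(exp+1)), permutation p; plus a binarised spatial
  gene-coherence statistic.
* **Synthetic data** — generators for all three data streams with planted,
  recoverable structure (known cell types, a planted cell-type→texture
  association, concentric perivascular niches, co-localised type pairs), so
  the whole pipeline is testable without any raw images.

## Worked example

Simulate a 30-FOV cohort with a planted CDK4-only → string-like texture
association, classify it, and run a scaled-down (3-replicate) SDM:

```python
from gbmspatial.synthetic import SimulationConfig, simulate_sdm_dataset
from gbmspatial.classify import classify_cells
from gbmspatial.diversity import diversity_by_group, cooccurrence_odds_ratio
from gbmspatial.sdm import quadrat_dataset, run_sdm_procedure, SDMConfig, SDM_CATEGORIES

config = SimulationConfig(n_fovs=30, seed=7)
cells, quadrat_labels, truth = simulate_sdm_dataset(config, seed=7)
classified = classify_cells(cells)

div = diversity_by_group(classified, "genotype_class")
orr = cooccurrence_odds_ratio(classified, "EGFR", "CDK4")

X, y, meta = quadrat_dataset(classified, quadrat_labels, 199.0,
                             fov_size=(config.fov_width, config.fov_height))
res = run_sdm_procedure(X, y, SDMConfig(n_replicates=3, seed=7),
                        class_names=sorted(meta["texture"].unique()),
                        feature_names=list(SDM_CATEGORIES))
```

Output:

```
7708 cells, 0 excluded
phenotype_class
tumor               5089
unclassified         697
EC-mimicry tumor     652
endothelial          641
immune               629
median per-FOV genotype Shannon index: 1.935
EGFR/CDK4 co-amplification OR: 1.89 [1.72, 2.08]
450 labeled quadrats
median overall macro AUC: 0.949
 cell_type  weighted_score    ci_low  ci_high
 CDK4-only        0.341632 -0.052479 0.735743
 EGFR-only        0.113580 -0.072677 0.299838
EC-mimicry        0.061406 -0.035589 0.158402
```

Reading it: with uniform type frequencies the per-FOV genotype diversity
sits near its ceiling (ln 8 ≈ 2.08 over the 8 genotype categories); the OR
close to 2 reflects that co-amplified categories (CDK4/EGFR, triple)
contribute cells positive for both genes; the SDM classifies textures well
above chance (macro AUC 0.95), and the planted CDK4-only association is the
strongest positive attribution for the string-like texture. (At 3
replicates the across-replicate CIs are wide; the replicated procedure uses
100 by default.)

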