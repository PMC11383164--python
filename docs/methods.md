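# Methods

This note documents the models, rules, and numerical choices behind
`gbmspatial`, and what the synthetic-data tests do and do not demonstrate.

## Cell classification

Input is per-nucleus segmentation output: FISH spot counts for *CDK4*,
*EGFR*, *PDGFRA*; a STAR-FISH spot count for the TERT-promoter mutation;
and boolean marker positivity (CD31, CD45RO, nuclear HIF1α).

* **Amplification**: count ≥ 6 (inclusive), per gene, echoing clinical
  HER2-FISH scoring. The genotype class is the subset of amplified genes
  (8 categories from `none` to `triple`).
* **Overlap exclusion**: any gene at ≥ 50 copies voids the nucleus (likely
  two overlapping nuclei); excluded cells carry no classes.
* **Mutation**: any STAR-FISH spot → MUT (the assay is specific; a single
  amplicon spot is evidence).
* **Phenotype precedence**: a cell is genetically tumor if it has any
  amplification or the mutation. Tumor ∧ CD31 → EC-mimicry tumor; tumor →
  tumor; CD45RO → immune; CD31 → endothelial; else unclassified. When a
  genetically normal cell is CD45RO⁺CD31⁺ we call it immune: CD45RO is
  lineage-defining while CD31 signal can bleed from adjacent vessel
  fragments. The precedence is configurable
  (`ClassificationScheme.immune_over_endothelial`).
* **Hypoxia** is a boolean modifier crossed with the base phenotype
  ("hypoxic EC-mimicry tumor"), not a competing class, so both marginal
  tabulations are available.

Unclassified cells are kept in spatial analyses (they contribute to local
density) but dropped from frequency/diversity tables by default.

Two-round QC (`qc_lost_nuclei`) greedily matches first-round nuclei to
second-round centroids within 5 px (shortest distance first, each target
used once); unmatched first-round nuclei are "lost". The radius is a
parameter — segmentation tables do not preserve the mask overlay that an
image-based check would use.

## Diversity and association statistics

Shannon index H = −Σ pᵢ ln pᵢ in nats (the ecology convention). The
co-amplification odds ratio uses the per-cell 2×2 amplification table with
a Haldane–Anscombe +0.5 on all cells whenever any count is zero, and a Wald
log-scale 95% CI; tables with an empty margin are flagged as having an
unbounded CI. OR-high/low tumor groups split at the cohort median (ties
low); an explicit threshold can override. Paired primary-vs-recurrent
comparisons use the exact two-sided Wilcoxon signed-rank distribution for
n ≤ 25 pairs, dropping zero differences. Cluster-vs-cluster contingency
uses one-sided (over-representation) Fisher exact tests, reported raw and
Benjamini–Hochberg adjusted. In place of proprietary regression-based
outlier removal before case averaging we flag values outside median ±
3.5 MAD (scaled); this is a deliberate substitution of a robust,
reproducible rule.

## Neighborhood features and clustering

Per cell and per class: Euclidean distance to the nearest cell of that
class (own class uses the nearest *other* cell). Exactly coincident
centroids are jittered by ≤ 0.5 px per axis before distance computation.
Classes absent from an FOV receive the FOV diagonal as a flagged sentinel.
Clustering is k-means (k fixed, or silhouette-selected over 2–10); a t-SNE
embedding is optional and off by default because it distorts distances.

## The quadrat species-distribution model

**Sampling units.** Each FOV is tiled by square quadrats (width 199 px by
default; 114/266/399 supported) with half-open bounds — a cell exactly on a
shared edge belongs to the right/lower quadrat — and partial edge quadrats
dropped. Each quadrat carries a 12-long count vector over {the 7 amplified
genotypes, TERTp-mutant, immune, endothelial, EC-mimicry, all-tumor
aggregate} and an ECM texture label (string-like / spotty / mossy) taken
from a per-quadrat label table or from a label mask at the quadrat center.

**Preprocessing.** Counts are min-max scaled per feature over the full
cohort *before* splitting (the default mirrors the common practice of
scaling once per data set; a no-leakage option scales on the training
split only). Splits are
0.8/0.1/0.1 with train size ⌊0.8n⌋. The training split is balanced by
SMOTE (k = 5 same-class neighbours, convex combinations); synthetic
samples never leave the training set and are excluded from every
evaluation and attribution.

**Network.** 12 → 36 (×10) → 24 → 12 → 3: thirteen weight layers, each
Linear → BatchNorm; hidden layers add leaky-ReLU (slope 0.01) and the
first eleven add inverted dropout with rates decreasing linearly from 0.15
to 0. The output layer has batch norm but no activation. He initialisation.
The implementation is plain NumPy with hand-written backprop (including
training-mode batch-norm gradients), which keeps the model's input
gradients exactly consistent with its forward pass.

**Loss and optimisation.** Class-balanced focal loss with β = 0.999,
γ = 2.0 (the defaults of the loss's original formulation; after SMOTE the
class weights are equal, but the loss is general), AdamW at lr 1e−3,
weight decay 1e−2 applied to weight matrices only, 11 mini-batches per
epoch. Early stopping makes the qualitative "train/validation divergence"
rule precise: stop when validation loss has not improved for 20 consecutive
epochs while the last-20-epoch training-loss slope is negative (or after a
100-epoch joint plateau, or at 400 epochs); the best-validation weights are
restored. Training is deterministic given the seed.

**Attribution.** Integrated Gradients for the predicted class against the
zero baseline (an empty quadrat on the scaled count scale), m = 64 by
default as a right Riemann sum. Because the inference-mode network is
piecewise linear, the package also implements `method="exact"`: activation
signatures locate the linear-region boundaries along the path (bisection to
1e−7), and the integral is summed segment-by-segment with the constant
per-segment gradient. This removes the O(1/m) quadrature error at
leaky-ReLU kinks (measured residuals: ~6e−3 mean at m = 256 for the plain
sum vs ~1e−6 for the exact path on a trained network), so the completeness
axiom ΣᵢIGᵢ = F_c(x) − F_c(x′) holds to near machine precision. The
replicated pipeline keeps the m = 64 Riemann sum — after pooling thousands
of quadrat attributions the quadrature bias is negligible — while
completeness is verified with the exact path.

**Replication and weighting.** The whole fit (fresh split → SMOTE → train
→ evaluate → attribute) is repeated n times (100 by default); re-drawing
the split each replicate lets quadrats misclassified by one model be
captured by another. For each (texture, cell type), attributions are pooled
over correctly classified real quadrats of that texture across replicates;
the score is mean(non-zero attributions) × (n_informative / n_correct),
with |a| > 1e−6 counting as non-zero. The 95% CI comes from the
across-replicate spread of per-replicate scores (undefined at one
replicate). Pooling across replicates (rather than averaging per-replicate
scores) is a documented choice; the per-replicate scores are what the CI
uses.

## Niche analysis

Cells with fewer than 5 genes detected at count ≥ 1 are dropped
(inclusive bounds). Normalisation scales each cell to the median library
size then log1p; per-gene z-scores are available for display. Cell typing
is the standard targeted-panel workflow: PCA (≤ 30 components) → shared
nearest-neighbour graph → Leiden; markers by Wilcoxon rank-sum vs rest with
BH adjustment. Niches: each cell's k = 30 exact nearest spatial neighbours
(self excluded, distance ties broken by cell index) are counted by type;
k-means (k-means++, fixed seed) groups the composition vectors into n
niches (7 by default; tests use the planted ring count). Raw
neighbour counts are the default feature (rows sum to k); frequencies are
an option. Over-represented (niche, type) pairs are flagged by a one-sided
binomial test of the niche count against the global type frequency at
α = 0.001. The binomial form of this outlier test is the package's design
choice; other reasonable tests (e.g. chi-squared residuals) would flag
similar sets.

## Proximity enrichment

The spatial network is the Delaunay triangulation of centroids with edges
longer than 50 px removed (collinear degeneracies fall back to a k = 6
kNN graph). For each unordered type pair: observed edge count vs the mean
over label permutations (1,000 by default; the network and type multiset
are fixed), enrichment log2((obs+1)/(exp+1)) with the raw ratio also
reported, and an add-one-corrected two-sided permutation p on the deviation
of the count from its permutation mean. On a complete graph the
permutation expectation has the hypergeometric closed form
E[count(a,b)] = |E|·2nₐn_b/(n(n−1)), which the tests use as an oracle.

The binarised gene statistic splits one gene's cells into high/low
(1-D 2-means on log1p counts, or a rank threshold) and measures high–high
adjacency via the directed-edge contingency table [[2hh, mixed],
[mixed, 2ll]]: OR = 4·hh·ll/mixed². The Fisher exact p on that table is the
field convention but anticonservative (edges share endpoints); a
permutation variant (`method="permutation"`) is provided and is the one
with calibrated false-positive rates.

## Synthetic data: what it emulates, and what it does not

The imaging generator produces ~90 FOVs of 995 × 597 px (15 quadrats of
199 px each, ~1,300 cohort-wide) with 150–400 cells per FOV across 12
generative cell types. Spot counts are drawn with mean = true copy number
(2 normal, 12 amplified) and variance = `copy_noise` × mean — 0 is
noiseless, 1 is Poisson, above 1 gamma-Poisson; the (0,1) range mixes the
exact value with a Poisson draw. At the Poisson default, a normal gene
crosses the 6-copy threshold with probability 0.017, so classification is
reliable but not perfect, as in real FISH. Within each FOV, per-quadrat
type compositions are Dirichlet-distributed (αᵢ = 0.5 at uniform base
frequencies) to mimic tissue patchiness; texture labels are sampled from
softmax(W·scaled counts + b) on the same min-max scale the SDM consumes, so
planted weights are interpretable on the model's input scale. The default
planted association (CDK4-only → string-like at weight 60, with weight-36
supports distinguishing the other two textures) was set so that the
*generative* Bayes ceiling of the label channel is ≈ 0.97 macro AUC —
softmax label sampling, not model capacity, is what limits accuracy, and a
"strong-signal" benchmark needs near-deterministic labels.

The transcriptomics generator places cells uniformly at 0.003 cells/px² on
a 1,500 × 1,500 px tissue with one vessel: three concentric rings
(vascular EC+fibroblast core, perivascular-macrophage ring, outer
mesenchymal/OPC shell) over a mixed background, 10 cell types, 70 genes
(6 private markers per type at mean 8 counts, baseline 0.2), negative
binomial with shared dispersion 0.5 — roughly the transcript yield of a
targeted in-situ panel. The co-ring placement of PVM and fibroblasts is
the planted attraction the proximity tests must recover.

Passing these tests shows the pipeline recovers planted structure under
idealised conditions: no segmentation errors, no marker intensity
ambiguity, no spatial autocorrelation beyond the planted one, texture
labels generated from exactly the counts the model sees, and isotropic
tissue. None of that guarantees performance on real images — in particular
the SDM's real-data accuracy depends on annotation quality and on how much
texture information the 12 composition features actually carry.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale as
the package's own benchmark sizes: ten 10-replicate SDM runs on a ~1,350
quadrat cohort for recovery, one 10-replicate null run, 50 × 1,000-cell
tissues for permutation calibration, and a ~6,600-cell tissue for niche
recovery. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds give byte-identical outputs,
including network training.
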