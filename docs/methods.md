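# Methods

## Problem and model

`spotmark` implements a bottom-up biomarker discovery workflow for
imaging-based spatial transcriptomics of tumors with mixed histology
(prototypically lung adenosquamous carcinoma, which intermixes adenocarcinoma
(ADC), squamous (SCC) and TTF-1⁻/p40⁻ components in one mass). The workflow
has two stages:

1. **Spatial stage.** From a cell-by-gene panel count matrix with per-cell
   geometry: normalize expression by cell area, cluster cells, call
   keratin-positive clusters as the tumor fraction, visualize transcriptional
   states as RGB colors on the tissue, audit and exclude histologically
   normal epithelial foci, screen tumor-specific genes by dropout-rate
   quadrants, and characterize them per histological subtype and by
   biweight-midcorrelation (bicor) coexpression.
2. **Bulk stage.** Project one selected marker onto a bulk cohort: median
   split, Kaplan–Meier curves with the log-rank test, a multivariable Cox
   proportional hazards model, and Fisher-exact mutation enrichment.

### Area normalization

Imaging-based platforms resolve expression per segmented cell, and tumor
cells are hypertrophic: transcript totals scale with cell area. Expression is
therefore rescaled to counts per 100 µm² of cell area,
`e[c,g] = 100 · x[c,g] / A_c`. The transform preserves the sparsity pattern
and is exactly invertible (multiplying back by `A_c/100` recovers the integer
counts), which the suite asserts as an identity. Detection calls
(positivity, dropout) always use raw counts — whether a transcript was seen
is not an abundance statement, and area scaling can never change it.

### Tumor-fraction calling

Cells are clustered by Leiden community detection on a k-nearest-neighbor
graph built in PCA space (defaults: 50 PCs, k = 15, resolution 1.0, all
overridable; the upstream on-instrument pipelines do not publish their
values). Clusters are renumbered 1..K in descending cell count. Per cluster,
the summed area-normalized expression of the two panel epithelial keratins
(KRT7 + KRT15, the panel-available proxy for pan-keratin AE1/AE3 IHC) is
compared with the mean over all other cells; a strictly positive log2 fold
change (pseudocount ε = 1e−9 guards empty complements) calls the cluster
keratin-positive. The tumor content estimate is the fraction of cells in
keratin-positive clusters; after ROI exclusion the pipeline reports the
corrected content with excluded normal cells removed from the numerator but
retained in the denominator, since they are still part of the section.

A deliberate failure mode is preserved: normal epithelial cells are
keratin-high and can land inside keratin-positive clusters, so keratin
calling alone overestimates tumor content. That is exactly the gap the ROI
audit closes.

The keratin notation "(KRT15/KRT7)" in upstream descriptions is ambiguous
between a two-keratin ratio and a vs-rest fold change; the summed-signal
vs-rest reading is implemented because it matches the pan-keratin IHC
analogy (either keratin marks epithelium; their ratio distinguishes lineages,
which is not what the tumor/non-tumor split needs).

### RGB-UMAP

Keratin-positive cells (only — the function asserts the flag) are reduced to
three components; each component is linearly rescaled to 0–255 (rounding half
away from zero; a degenerate constant channel maps to 0) and assigned to the
red, green and blue channels in component order. Colors are then drawn at the
original tissue coordinates. Because channel scaling is min–max, the map is
invariant to positive affine transforms of a component and no outlier
clipping is applied. The embedding backend is pluggable: the default is a
UMAP reducer with a fixed seed; a deterministic PCA backend is provided for
fast exact tests. Embeddings are computed per sample and never compared
across samples — colors encode within-sample relationships only.

The treemap summary tiles the tissue bounding box into a regular grid
(default 8×8) and reports, per tile and cluster, the cell count and mean RGB.
Tiles are half-open `[lo, hi)` in x then y; the global max edge falls into
the last tile so counts conserve exactly.

### ROI audit

Cells are assigned to annotated ROIs by point-in-polygon tests with the
boundary counted as inside; overlapping ROI polygons are rejected, otherwise
first match in file order wins. For an audit gene (default the EPCAM-like
epithelial marker), positivity (raw count ≥ 1) inside vs outside the ROI is
tested per cluster with a two-sided Fisher exact test and Benjamini–Hochberg
correction across clusters (a pooled single-table mode is also provided,
since whether per-cluster or pooled testing is the better reading of the
source analysis is open). Flagged ROIs are excluded; exclusion conserves
cells (|input| = |kept| + |log|) and is idempotent.

### Dropout-rate marker screen

The dropout rate of a gene in a fraction is the proportion of cells with
zero raw transcripts. With tumor = keratin-positive post-exclusion cells and
non-tumor = keratin-negative cells, the plane (d_N, d_T) is cut at τ = 0.75
into four categories: tumor-specific (d_T < τ ≤ d_N), normal-specific
(converse), common-positive (both < τ), common-negative (both ≥ τ). The
expressed side is strict and the dropout side inclusive; boundary mass is
negligible at realistic n, but the convention makes the rule a total
function on [0,1]². Candidates are ranked by total raw expression in tumor
cells (ties alphabetical); ranking is over all genes by default with a
strict tumor-specific-only variant, because high-expression lists in this
workflow mix categories by construction. Per-cluster summaries z-score the
cluster means gene-wise using the population-SD convention (ddof = 0,
recorded in run metadata; sample-SD is available via a parameter). Samples
are compared by plain set intersection of their tumor-specific lists.

The alternative screening flow in which some keratin-positive clusters are
histologically normal (and should count as non-tumor) is supported by
passing per-cluster overrides of the tumor mask.

### Bicor coexpression

Biweight midcorrelation is implemented from its published definition:
`u_i = (x_i − med_x)/(9·MAD_x)` with unscaled MAD, Tukey biweights
`w_i = (1 − u_i²)²·1[|u_i|<1]`, correlation of the weighted centered
vectors, clamped to [−1,1]. A variable with zero MAD carries no biweight
information and falls back to Pearson centering for its pairs, flagged in
the output. Networks keep undirected signed edges with |bicor| ≥ 0.2 by
default (a threshold is needed to discretize an all-pairs correlation
field; configurable). Correlation runs on area-normalized expression for
consistency with the rest of the pipeline; raw counts are accepted too.
Subtype populations are pooled across samples before correlation.

### Bulk projection

The marker's bulk expression is dichotomized at the cohort median with ties
to the low group ("high" is strictly above the cutoff). Kaplan–Meier
estimation, the two-group log-rank test and the Cox model use standard
partial-likelihood machinery with Efron tie handling (lower bias than
Breslow under ties). Stage enters the default model as a binary I/II vs
III/IV indicator, matching the subgroup axes of the analysis; full ordinal
coding is available. Subgroup analyses (stage strata, EGFR/KRAS wild-type)
filter rows after the full-cohort median split by default, so the cutoff has
one meaning across panels; the choice is recorded in result metadata.
Mutation-flag enrichment uses the two-sided Fisher exact test with the
conditional-MLE odds ratio and BH q-values.

## Synthetic data

Real datasets of this kind are controlled-access, so a first-class generator
reproduces the statistical structure the analysis assumes, with ground truth
for recovery tests.

**Tissue.** A 3000×2000 µm domain holds four rectangular blocks (ADC, SCC,
TTF-1⁻/p40⁻, stroma) and two circular normal-epithelium foci of radius
250 µm (two normal regions mirror the discovery sample's annotation).
Cells are placed by a homogeneous Poisson process per region (densities
11/9/8/13/12 cells per 10⁴ µm² for ADC/SCC/TTF/stroma/normal — chosen to
yield ≈5300 cells with a tumor fraction near 0.63, in the range purities
reported for resected tumors). Cell areas are log-normal per label with
tumor median 180 µm² vs stromal 95 µm² (tumor hypertrophy); nucleus area is
a uniform 15–45% fraction of cell area.

**Counts.** Gene counts are Poisson with mean `rate × area/100` (rates in
counts per 100 µm²), the simplest model that reproduces the area–transcript
relationship and yields controllable dropout through the Poisson zero mass;
optional per-gene zero inflation and a shared log-normal latent factor
(E = 1) add excess dropout and within-subtype coexpression. All streams
derive from one seed by fixed offsets.

**Panel.** 120 genes, a desk-scale stand-in for a ~400-gene lung panel:
20 planted tumor-specific genes (KRT7, KRT15, an EPCAM-like and a
GLUT1-like/SLC2A1 anchor plus 16 lineage signature genes split pan-tumor /
ADC-high / SCC-high / TTF-shared), 20 common-positive (four named for the
canonical mesenchymal genes they mimic), 20 common-negative, 10
stroma-specific, and 50 housekeeping fillers with moderate label-varying
rates. Rates are free parameters chosen once to place each planted gene
clearly in its intended dropout quadrant at the default geometry; the
SLC2A1-like gene is monotone SCC > TTF-1⁻/p40⁻ > ADC and near-zero in
normal epithelium, and carries a shared latent factor with two SCC-skewed
partners in the squamous-featured labels only. Normal-focus rates copy the
ADC profile except for the planted exceptions (EPCAM down ~20-fold, SLC2A1
off), so normal cells co-cluster with tumor cells — the failure mode the
ROI audit must catch — while remaining separable by the positivity audit.

**Bulk cohort.** Marker expression is log-normal; survival times are
exponential with log-hazard β·1[expr > median] plus linear covariate
effects (stage III/IV log 1.8, age 0.015/yr, smoking log 1.3, sex log 1.1 —
magnitudes typical of adjusted lung-cancer survival models); baseline median
survival 40 months. Censoring is independent Uniform(0, C) with C calibrated
by root-finding so the expected censored fraction matches the requested rate
(default 0.3). Mutation flags are Bernoulli with marker-group-dependent
rates (squamous-associated genes enriched in the high group, EGFR in the
low group). Default cohort size 722 mirrors the scale of a published
institutional cohort (574 ADC + 148 SCC).

**What the generator does not emulate.** No spatial autocorrelation of
expression within a region beyond label effects, no segmentation errors or
doublets, no cross-gene negative binomial overdispersion, no batch effects,
and mutation flags are independent Bernoulli rather than co-occurring
lesions. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under its stated assumptions, not robustness to every
artifact of real imaging data.

## Numerical choices and degenerate inputs

- Keratin fold change: ε = 1e−9 pseudocount; flag rule strictly `> 0`.
- RGB rounding: nearest integer, half away from zero; constant channel → 0.
- Median split: ties to low; an all-constant marker is an error.
- Quadrant boundary: strict `< τ` on the expressed side.
- z-scores: population SD (ddof = 0) across cluster means; a single cluster
  is an error; constant rows map to 0.
- bicor: tuning constant 9, unscaled MAD, result clamped; zero-MAD variables
  fall back to Pearson with a flag; fewer than 4 observations is an error.
- Clustering: all-identical rows short-circuit to one cluster (PCA of a
  zero-variance matrix is undefined); n_pcs is reduced with a warning when
  cells or genes are too few.
- Censoring calibration solves `E[min(T/C, 1)] = rate` on the realized event
  times by Brent's method.
- Cluster count at the default resolution is data-dependent: Leiden
  subdivides large homogeneous populations, so the default tissue yields
  more clusters than labels; correctness is judged by label purity and
  keratin-call accuracy, not by the raw cluster count.

## Problem sizes

Default analyses run at ~5300 cells × 120 genes for the spatial stage and
722–1000 patients for the bulk stage, with 50-replicate coverage experiments
for the Cox interval; these sizes keep a full run on one CPU in minutes
while leaving all planted-recovery margins wide.

## Known limitations

- The keratin call is binary per cluster; partial-epithelial clusters are
  not modeled.
- Dropout screening ignores within-fraction heterogeneity: a gene expressed
  in one tumor subtype only still screens tumor-specific if its pooled
  dropout clears τ.
- The default grid treemap approximates the source's hand-drawn observation
  blocks with regular tiles.
- External network/enrichment services (gene-association networks, PPI,
  pathway enrichment) are out of scope; the bicor networks accept any
  user-supplied gene list, such as one derived from those services.
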