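# Methods

`ccatlas` re-implements, as tested reusable code, the bespoke computations of a
case/control droplet scRNA-seq study design: ambient-RNA background
subtraction with a QC filter cascade, filtered Wilcoxon differential gene
expression (DGE), a ligand–receptor interaction-potential permutation test,
post-processing of bulk deconvolution estimates, and signature-stability
resampling. Conditions are arbitrary labels with one designated *case*; the
motivating application is necrotizing enterocolitis (NEC) versus neonatal
intestinal tissue, but nothing in the code is specific to it.

## Ambient background and QC cascade (`ccatlas.qc`)

Cell-free ("ambient") transcripts contaminate every droplet. Background
droplets are defined per patient library as those with 100–300 total UMIs
(inclusive) and raw mitochondrial fraction below 50%; the per-gene mean UMI
count over these droplets is subtracted from every other droplet, clipping at
zero, and the background droplets are discarded. Two filter stages follow:

* stage 1 (per sample): cells with fewer than 200 expressed genes are
  removed, then genes expressed in fewer than 3 remaining cells;
* stage 2 (after merging samples on the union of surviving genes): cells
  with <1,900 UMIs, <1,000 expressed genes, mitochondrial fraction >30%, or
  erythrocyte-marker fraction >10% (markers HBG2, HBA2, HBA1, HBB, HBG1, HBM,
  AHSP, HBZ) are removed.

"Expressed" means strictly positive (post-subtraction values are fractional);
"less than"/"above" filters are strict; the background window is inclusive.
Background estimation and stage 1 run per patient library; whether subtraction
should instead pool a global background is an open design point — per-sample
is implemented because the cascade is narrated sample-wise before merging.
Mitochondrial fractions use raw counts for background detection and current
(post-subtraction) values at stage 2. Sum-normalization divides each cell by
its total, so all downstream thresholds (1e-4, 5e-5, 5e-6) live on the
per-cell fraction scale.

## Differential expression (`ccatlas.dge`)

Within one cell type, genes enter the comparison when (a) their mean
sum-normalized expression over all cells of the type, conditions pooled,
exceeds 1e-4 (5e-5 for sparse types), and (b) they are expressed in ≥5 cells
in each of ≥2 subjects. Retained genes get a two-sided Wilcoxon rank-sum
p-value between case and control cells — exact enumeration when both groups
have ≤8 tie-free observations, otherwise the tie-corrected normal
approximation with continuity correction — and Benjamini–Hochberg q-values
within that one comparison's gene family. Fold change is the ratio of
condition means with a pseudocount ε = 1e-6 (one order below the smallest
stated expression threshold); selection requires q < 0.02 and fold change
above the figure-level threshold (2 or 3) or below its reciprocal.

One-vs-rest marker finding uses a natural-log mean ratio (threshold 1.0 with
≥50% in-cluster expression at the cluster level; 0.6/25% for subtypes — the
log base of the upstream convention is not pinned, natural log is used
consistently). Annotation transfer assigns each query cluster the reference
name whose top-marker set has the highest summed mean expression, ties broken
lexicographically. The gene-set signature test scores each cell by the mean
normalized expression over the set (a curated 92-gene REACTOME TLR4-signalling
list ships as a packaged resource) and compares conditions by rank-sum. A
two-sided Fisher exact test serves per-cell positive-fraction comparisons,
and DGE tables export as GSEA-preranked `.rnk` files (descending log2 fold
change, lexicographic tie-break).

## Ligand–receptor permutation test (`ccatlas.lr`)

For sender type A, receiver type B and ligand/receptor pair (L, R), the
interaction potential of a condition is the product of the mean sum-normalized
expression of L over A-cells and of R over B-cells; potentials therefore live
in [0,1]². Candidates require the ligand (and, mirrored, the receptor) to be
expressed in ≥10 cells and ≥10% of the type's cells within at least one
condition; all ordered type pairs, self-pairs included, are screened. The
observed statistic is the case/control potential ratio with ε = 1e-9 added to
both potentials (far below any mean passing the expression filter). The null
re-assigns cells to conditions at random *within each cell subtype*,
preserving per-subtype condition counts; 100 relabelings by default, one
shared relabeling per replicate (subtypes processed in sorted order, one RNG
permutation each — pinned so an independent implementation can reproduce the
draw stream). The standardized ratio z = (ratio − mean of randomized ratios) /
sd (ddof = 1) converts to a one-sided upper-tail normal p; depletion is probed
by swapping condition roles (`--direction control-over-case`). Zero-sd nulls
take the limiting p (0, 0.5 or 1) and are flagged. BH correction runs over all
candidates of the run; per type pair, records with q < 0.01 are sorted by
ratio (descending, lexicographic tie-break) and the top 25 kept.

## Deconvolution post-processing (`ccatlas.composition`)

The annealing optimizer that estimates proportions from bulk RNA-seq is
external by design; this module builds its signature input (per-type mean
normalized expression, with an optional merge map for pooling subsets that
split by disease status), screens its output samples (retain a sample iff the
Spearman correlation between its bulk profile and the proportion-weighted
synthetic reconstruction exceeds 0.3; ties use average ranks and undefined
correlations fail the threshold), applies the two-tier display normalization
(major types over the grand total, remaining types over the total excluding
the majors) and within-group renormalization (zero-sum groups yield missing
values with a warning), and compares per-type proportions between conditions
with rank-sum tests and BH correction scoped to the declared family. Fold
changes use condition means with ε = 1e-6 (the estimator is not pinned by the
source procedure; means are linear in the deconvolution output). The
imaging-derived adjacency ranking drops rows/columns touching the "other"
label, computes per-ordered-pair case − control differences, and stacks the
top-k pairs with positive case values (descending difference) and bottom-k
with negative case values (ascending difference).

## Stability curves (`ccatlas.stability`)

The reference signature is the per-type mean normalized profile over one
condition's cells, with a per-type gene mask keeping genes above 5e-6. The
mask is fixed by the reference and reused for every subsample so curves stay
comparable; it is per cell type (not global) because correlations are
computed per type. For each patient count n, every patient combination is
bootstrapped (cells resampled with replacement within the selected patients —
the bootstrap unit is the cell, a design choice since the source procedure
does not define it) 3 times; the full-patient point bootstraps all cells.
Cell types lacking ≥10 cells in ≥4 patients are excluded (the pipeline caps
the patient requirement at the number of available patients for small
cohorts). The control design draws equally sized cell subsets (without
replacement, 20 bootstraps, median summary) ignoring patient identity, at
sizes matched to the mean depth of each patient-count stratum, separating the
effect of patient count from cell count. Reference signatures and masks are
invariant to gene and cell ordering; bootstrap draws depend on cell order
through the RNG, so curves are order-invariant in distribution, not
realization.

## Synthetic data (`ccatlas.synthetic`)

The generator emulates a multi-patient two-condition atlas: negative-binomial
counts (gamma–Poisson, shared dispersion r = 10) with cell-type-specific
means, per-gene baseline means lognormal around 2.0 (σ = 1.0 — real gene
means span orders of magnitude, and a near-constant ambient profile would
make rank-correlation recovery meaningless), 20 markers per type at fold 8,
10 mitochondrial genes ("MT-" prefix) at 8× baseline and the 8 erythrocyte
genes at baseline, mean-one lognormal library sizes (σ = 0.25), patient-level
mean jitter (mean-one lognormal, σ = 0.05 per patient × gene), 10% ambient
contamination mixed so the expected library size is preserved, 40 empty
droplets per patient with uniform 100–300 UMI totals and multinomial ambient
composition, and planted high-mito (50%) / high-erythrocyte (25%) QC-failure
cells. The ambient profile is the expression-weighted mean of all real cells'
expected profiles. Planted DE genes multiply a gene's mean in case cells of
one type; planted ligand–receptor pairs boost ligand/receptor means in the
sender/receiver type's case cells. Genes participating in planted effects are
pinned to the exact baseline mean so folds are not confounded with the random
mean draw. Truth tables are bookkeeping, not estimation: expected profiles,
ambient composition, droplet and QC-failure labels, and planted lists are
emitted exactly.

What the generator does **not** model: doublets, UMI-level sequencing error,
batch effects beyond patient mean jitter, zero-inflation beyond the NB, or a
realistic gene–gene correlation structure. Passing tests therefore certify
the statistical machinery under its stated assumptions, not performance on
real tissue data.

## Calibration experiments and the pseudo-replication caveat

Both the permutation null (exchangeability within subtype) and the cell-level
rank-sum test (independence within condition) assume cells are exchangeable
units. Patient-level jitter violates that: cells from one patient are
correlated, and with few patients per arm the cell-level tests are
anti-conservative (with the default σ = 0.05 jitter, the null ligand–receptor
p < 0.05 fraction measures ≈0.12 and the DGE false-discovery proportion
≈0.11). This is a property of the published procedure under patient
structure, and users analyzing strongly patient-structured data should
interpret cell-level q-values accordingly (or aggregate to pseudo-bulk).
Calibration and FDP are therefore measured in the exchangeable regime
(jitter 0; the DGE run also disables ambient mixing to isolate the testing
machinery), where the LR null fraction sits at ≈0.03–0.07 and the DGE FDP at
≈0.02–0.05 with sensitivity 1.0. Recovery and stability experiments keep the
default jitter.

A related scale note: because the synthetic ambient mixture preserves library
size, ambient correction is judged on each type's mean expression
*composition* (profile normalized to sum 1 — the scale every downstream
statistic uses), where subtraction strictly reduces RMSE to truth; on raw
counts the ~200-UMI background mean under-corrects the ~440-UMI ambient
content of a typical cell and the comparison conflates scale with
composition.

## Numerical conventions

* Fold-change pseudocounts: 1e-6 on sum-normalized means (DGE, proportions);
  1e-9 on interaction potentials.
* Randomized-ratio sd uses ddof = 1; 100 permutations by default (≥2
  required).
* Sorting is always stabilized (mergesort) with lexicographic tie-breaks, so
  every output file is byte-reproducible for a fixed seed.
* Degenerate inputs raise informative errors rather than propagating NaNs:
  all-zero cells at normalization, empty background windows (subtraction is
  then skipped and flagged), empty gene masks, missing conditions (a cell
  type absent from one condition is skipped with a warning at the pipeline
  level, mirroring comparisons dropped for underrepresentation).

## Problem sizes used in the shipped experiments

The default synthetic atlas is 4 types × 100 cells × (5+5) patients ≈ 4,400
droplets × 2,000 genes. Recovery experiments use 20 seeds each: DGE at 2
types × 50 cells × (3+3) patients, ligand–receptor at 10 cells/type/patient
(50 per type per condition) with 8 planted pairs and 17 decoys. Calibration
uses one full-size null atlas with 1,000 permutations (≈380 candidates);
stability uses the full default atlas. These sizes were chosen so the whole
suite and the reproduction script each complete in well under an hour on a
laptop core while leaving every acceptance band comfortably resolved.
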