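# ccatlas

Reusable, tested building blocks for a **case/control droplet scRNA-seq atlas
study** — the kind of analysis that compares diseased and unaffected tissue
across a handful of patients, such as necrotizing enterocolitis (NEC) versus
neonatal small intestine. The package is aimed at computational biologists
who need the bespoke statistics of such studies as auditable library code
rather than one-off scripts:

* **Ambient-RNA background subtraction and QC** — background droplets are
  those with 100–300 UMIs and mitochondrial fraction <50%; their per-gene mean
  is subtracted from all cells (clipped at zero), followed by the filter
  cascade (<200 expressed genes, genes in <3 cells per sample; then <1,900
  UMIs, <1,000 genes, >30% mitochondrial or >10% erythrocyte fraction after
  merging) and per-cell sum-normalization.
* **Filtered Wilcoxon differential expression** — genes with mean normalized
  expression >1e-4 and expressed in ≥5 cells of ≥2 subjects, two-sided
  rank-sum p-values, Benjamini–Hochberg q-values, fold-change/q selection
  flags, marker finding, reference-marker annotation transfer, gene-set
  signature testing (a 92-gene REACTOME TLR4 list ships with the package),
  Fisher exact proportion tests, and GSEA `.rnk` export.
* **Ligand–receptor crosstalk** — for sender type A, receiver type B and pair
  (L, R), the *interaction potential* per condition is

  `potential = mean(L | A-cells) x mean(R | B-cells)`

  on sum-normalized expression. The case/control potential ratio *r* is
  standardized against randomized ratios from condition-label permutations
  within each cell subtype (100 by default), `z = (r - mean(r_rand)) /
  sd(r_rand)`, with one-sided normal-tail p-values, BH q-values, and per
  type pair the top 25 interactions at q < 0.01 sorted by ratio.
* **Deconvolution post-processing** — per-type signature construction, the
  Spearman > 0.3 reconstruction filter for bulk samples, two-tier and
  within-group proportion renormalizations, grouped rank-sum/FDR comparisons,
  and the imaging adjacency-difference ranking (drop "other", top/bottom 20
  signed differences).
* **Signature stability** — Spearman correlation of per-type expression
  signatures (genes above 5e-6) between patient-combination/cell-subsample
  bootstraps and the full-condition reference.
* **Synthetic atlas generator** — negative-binomial counts with marker
  structure, ambient contamination, 100–300-UMI empty droplets, planted
  QC failures, planted DE genes and planted ligand–receptor effects, with
  exact ground-truth tables, so every stage above is testable end to end
  without any external download.

## Worked example

Plant one up-regulated ligand–receptor interaction, run QC, and test it:

```python
from ccatlas.synthetic import SyntheticSpec, PlantedLR, generate_atlas, generate_lr_table
from ccatlas.qc import run_qc, sum_normalize
from ccatlas.lr import LRParams, candidate_interactions, permutation_test, top_interactions

planted = [PlantedLR("G0001", "G0002", sender="type1", receiver="type2",
                     ligand_fold=5.0, receptor_fold=1.0)]
spec = SyntheticSpec(cells_per_type_per_patient=25, planted_lr=planted, seed=0)
adata, truth = generate_atlas(spec)
print(f"atlas: {adata.n_obs} droplets x {adata.n_vars} genes")

clean, report = run_qc(adata)
print(f"after QC: {clean.n_obs} cells x {clean.n_vars} genes")

norm = sum_normalize(clean)
pairs = generate_lr_table(spec, n_null_pairs=10, seed=1)
params = LRParams(n_permutations=100, seed=2)
cands = candidate_interactions(norm, pairs, params)
records = permutation_test(norm, cands, params)
print(f"{len(cands)} candidate interactions tested")

row = records[(records.sender == "type1") & (records.receiver == "type2")
              & (records.ligand == "G0001") & (records.receptor == "G0002")].iloc[0]
print(f"planted pair: ratio={row.ratio:.2f}, z={row.z:.2f}, p={row.p:.2e}, q={row.q:.2e}")
```

prints

```
atlas: 1460 droplets x 2000 genes
after QC: 986 cells x 2000 genes
176 candidate interactions tested
planted pair: ratio=3.56, z=15.46, p=3.10e-54, q=1.37e-52
```

The 1,460 droplets are 1,000 real cells + 60 planted QC failures + 400 empty
droplets; QC removes the empties and failures (and subtracts the ambient
profile they estimate). The planted fivefold ligand boost survives as an
observed potential ratio of ≈3.6 — ambient contamination and QC dilute the
planted effect — and stands at ~15 standard deviations above the permutation
null, while in this run no decoy pair reaches q < 0.01.

The same stages are scriptable from the shell:

```bash
ccatlas simulate --out-dir data --seed 0
ccatlas qc --counts data/matrix.mtx --metadata data/metadata.tsv --out-dir clean
ccatlas lr --counts data/matrix.mtx --metadata data/metadata.tsv \
           --pairs data/lr_pairs.tsv --out lr.csv --permutations 100 --seed 2
ccatlas run --config pipeline.yaml   # full pipeline with manifest
```

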