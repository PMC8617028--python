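# tme-atlas

A toolkit for the bespoke computations of multi-omic tumor-microenvironment
studies of the kind done on multi-patient spinal-ependymoma cohorts
(scRNA-seq + scATAC-seq + histone-mark ChIP-seq). It packages, as tested and
reusable library code, the statistics that such studies usually re-implement
ad hoc:

- **Cell QC and normalization** — the five-rule filtration cascade
  (total UMIs, detected genes, mitochondrial fraction, and the two
  doublet ceilings), median library-size normalization with log1p,
  binned-dispersion HVG selection, and OLS covariate residualization.
- **Expression-inferred CNV** — per-gene centering on a nonmalignant
  baseline, a moving average along the genome (101-gene window, ±3
  clipping), baseline-profile subtraction, and a mean-squared-profile
  score with a baseline-quantile malignant/nonmalignant call.
- **Patient mixability** — per-cell Shannon entropy of the patient
  composition among the k = 80 nearest embedding neighbors,

      H_i = − Σ_d p_i^d · log2 p_i^d,  Σ_d p_i^d = 1,

  with a 25,000-cell subsample, so H_i = 0 means a patient-private
  neighborhood and H_i = log2 D means perfect cross-patient mixing.
- **Signatures** — gene-set scores as plain means of log-normalized
  expression, 0–1 scaling, one-vs-rest Wilcoxon rank-sum marker tables
  with BH correction, DEG filters (log2FC > 0.2, adjusted P < 0.05,
  expressed = nonzero in ≥ 10% of cells), top-50 signature aggregation
  with cross-dataset Pearson correlation, Spearman reference-centroid
  label transfer (e.g. monocyte- vs microglia-derived TAM origins), and
  druggable-gene intersection that drops the "druggable genome"
  catch-all category.
- **scATAC + ChIP** — Tn5 insertion counting (fragment start and
  end−1), the cells × 2.5 kb-window matrix, the five-rule ATAC cell QC,
  TF-IDF weighting with idf_f = ln(1 + n_cells/n_cells_with_f),
  truncated-SVD LSI (components 2–30), gene-activity scores (gene body
  + 2 kb upstream), active-promoter calling (H3K4me3 within 1000 bp of
  a TSS overlapping H3K27ac), and r ≥ 0.15 co-accessibility networks.
- **Synthetic cohorts** — a negative-binomial generator with planted
  arm-level CNVs, disjoint marker programs, designed mixing regimes,
  per-cell-type accessible windows and designed active promoters, so
  every stage is testable without controlled-access patient data.

## Worked example

```sh
tme-atlas run --out-dir demo --seed 3
```

generates a 15-patient, 3000-cell cohort on a ~200-gene toy genome and
runs every stage. The printed report ends with (abridged):

```
## qc
- n_cells_in: 3000
- n_cells_kept: 2982
## cnv
- malignant_recall: 0.9756
## entropy
- mean_H: {'separated': 0.0, 'mixed': 3.7947}
## promoters
- n_called: 30
- n_designed: 30
- n_recovered: 30
```

Reading it: 18 of 3000 cells fail QC (mostly planted doublet-like
cells over the 70,000-UMI ceiling); 97.6% of the truly malignant cells
are recalled from the planted chr22 loss at the default baseline
quantile; mean neighborhood entropy is 0 bits when each patient's cells
cluster apart and ≈ log2 15 ≈ 3.91 bits when the 15 patients mix; and
all 30 genes designed to carry joint H3K4me3/H3K27ac promoter marks are
recovered, with no false calls.

The same stages are available individually (`tme-atlas simulate | qc |
entropy | atac | promoters`) on MTX/TSV/BED/fragments inputs, and as
plain library functions (`tme_atlas.infer_cnv`, `tme_atlas.mixability`,
`tme_atlas.tfidf_transform`, ...).

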