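# sclctools

A single-cell analysis toolkit for dissecting tumor heterogeneity in
small-cell lung cancer (SCLC) from UMI count matrices, aimed at
computational biologists working with scRNA-seq of solid tumors and the
matched bulk expression cohorts used to validate them.

SCLC tumors mix malignant cells — classified into molecular subtypes by
the dominant lineage transcription factor among *ASCL1* (SCLC-A),
*NEUROD1* (SCLC-N), *POU2F3* (SCLC-P) and *YAP1* (SCLC-Y), with an
*ASCL1*/*NEUROD1* co-expressing SCLC-A/N state and a non-neuroendocrine
(non-NE) fraction expressing none of the four — with immune and stromal
cells whose composition shapes therapy response. `sclctools` implements
the full expression-level workflow around that biology:

- **QC**: removal of cells with < 1000 detected genes or < 1000 UMIs,
  plus a top-1%-by-total-UMI doublet filter.
- **CNV inference**: per-gene residuals against a normal-epithelial
  reference, smoothed by a centered 100-gene moving average within each
  chromosome; malignant cells called from CNV burden
  (mean squared log-ratio) against the reference null.
- **Programs**: top-2000 variable genes → hypergeometric hallmark
  enrichment → Pearson-correlation grouping of the top hallmarks into
  proliferation / immune / hypoxia programs → per-cell scores as the
  mean z-scored expression of up to 45 program genes.
- **GSEA**: preranked weighted Kolmogorov–Smirnov enrichment score with
  gene-set permutation null (ES, NES, nominal p, FDR), and a per-cell
  ssGSEA score.
- **Subtyping and ITH**: per-cell TF truth-table classification,
  tumor-level dominance rules, Shannon-entropy intratumor-heterogeneity
  (ITH) metric, and immune hot/cold classification of bulk samples.
- **Microenvironment**: marker-mean deconvolution (MCP-counter style,
  10 populations), CellPhoneDB-style ligand–receptor permutation tests
  between clusters, a k-BET-style kNN chi-square batch-rejection rate,
  and a CytoTRACE-style gene-counts differentiation score.
- **Synthetic cohorts**: a generator that plants CNV segments, subtype
  mixtures, program activities, marker blocks, ligand–receptor pairs
  and batch shifts under negative-binomial UMI noise, emitting ground
  truth for every recovery test in the suite.

## Worked example

```python
from sclctools import (SimConfig, generate_dataset, filter_cells, normalize,
                       infer_cnv_profiles, call_malignant, classify_cell_subtype,
                       classify_tumor_subtype, subtype_heterogeneity, program_score)

cfg = SimConfig(seed=1)                      # 3 patients, 6 compartments
cm, ann, sets, truth = generate_dataset(cfg)
filtered, report = filter_cells(cm, min_genes=500, min_umis=1000)

# CNV-validate the epithelial cells against the normal-epithelial reference
epi = filtered.subset_cells(
    filtered.cell_meta["label"].isin(["malignant", "normal_epithelial"]).to_numpy())
expr = normalize(epi)
ref = epi.cell_ids[(epi.cell_meta["label"] == "normal_epithelial").to_numpy()]
calls = call_malignant(infer_cnv_profiles(expr, ann, ref, window=100))

labels = classify_cell_subtype(expr)
for patient in ["P1", "P2", "P3"]:
    mask = calls.malignant.to_numpy() & (epi.cell_meta["patient"] == patient).to_numpy()
    tumor, fractions = classify_tumor_subtype(labels.to_numpy()[mask])
    entropy, het = subtype_heterogeneity(fractions)
```

Output:

```
cohort: 2000 genes x 1380 cells, 3 patients
QC: retained 1366/1380 cells
CNV: 594/771 epithelial cells malignant (separation 30.1 null sds)
P1: SCLC-A, entropy 0.67 bits, heterogeneous
P2: SCLC-A/N, entropy 1.80 bits, heterogeneous
P3: SCLC-P, entropy 0.97 bits, heterogeneous
proliferation score range: -0.77 to 0.98
```

Reading the numbers: 14 low-depth/doublet cells are filtered; of the 771
epithelial cells, the CNV burden of 594 sits far above the reference
null (the separation statistic is the distance of the malignant burden
center from the reference mean, in reference-sd units), recovering the
600 planted malignant cells minus those lost to QC. The per-tumor calls
recover the configured subtype mixtures — P1 mostly SCLC-A with a
non-NE fraction, P2 an *ASCL1*/*NEUROD1* mixed tumor, P3 SCLC-P — and
the entropy (in bits, over the six labels) quantifies the intratumor
subtype heterogeneity. Program scores are mean z-scores, centered at 0
across cells.

The same stages are exposed as a CLI
(`sclctools simulate|qc|deg|cnv|score|gsea|subtype|hotcold|deconv|interactions|diffscore`)
over plain-text formats: Matrix Market MTX with gene/barcode/metadata
TSV sidecars, GMT gene sets, TSV tables and JSON summaries.

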