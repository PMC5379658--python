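# tnbc-concord

Molecular subtyping of triple-negative breast cancer (TNBC) from RNA-seq,
and the statistics needed to trust those calls when the RNA comes from
formalin-fixed paraffin-embedded (FFPE) tissue instead of fresh-frozen
(FF) tissue.

TNBC lacks the receptor targets that guide therapy in other breast
cancers; treatment decisions can instead lean on transcriptional
subtypes (BL1, BL2, M, LAR, ...) called by correlating a tumor's
expression profile against per-subtype reference centroids.  Clinical
specimens, however, are FFPE: the RNA is degraded, cannot be poly-A
selected, and is sequenced with ribosomal depletion — so its
transcriptome systematically differs from the FF material the
classifiers were trained on.  This package implements the full
analysis framework for quantifying whether subtype calls survive that
change of preparation, platform, and sequencing depth:

* **Nearest-centroid subtyping** (`tnbc_concord.subtyping`) — FPKM
  normalization, Spearman (or Pearson) correlation of each sample
  against every centroid on log2(FPKM+1), a subtype call with
  **prediction strength** (the winning correlation ρ₍₁₎) and
  **prediction confidence** (ρ₍₁₎ − ρ₍₂₎, the gap to the runner-up),
  an UNCLASSIFIED outcome for weak profiles, and centroid gene-set
  reduction.
* **Paired concordance statistics** (`tnbc_concord.concordance`) —
  agreement rate between paired calls with the two-sided exact
  Clopper–Pearson binomial interval, the accuracy-vs-confidence
  operating curve with the minimum cutoff achieving a target accuracy,
  per-pair Spearman expression correlations, and exact/asymptotic
  Mann–Whitney U group comparisons.
* **Differential-transcript identification** (`tnbc_concord.diffexpr`)
  — a self-contained negative-binomial Wald test (median-of-ratios
  size factors, method-of-moments dispersion, delta-method standard
  errors, Benjamini–Hochberg FDR) with the standard thresholds
  (|FC| ≥ 2, q ≤ 0.05, mean count > 4), plus the removal experiment:
  do paired correlations improve once preparation-dependent
  transcripts are dropped?
* **Bias characterization** (`tnbc_concord.transcript_bias`) —
  per-transcript-class accounting of the differential set,
  transcript-length bias testing, an exon-level 3′ positional-bias
  statistic (poly-A selection inflates 3′ coverage), hypergeometric
  gene-set overrepresentation with FDR q-values, and read-category /
  rRNA-fraction library summaries.
* **A synthetic paired-cohort generator** (`tnbc_concord.synthetic_data`)
  — negative-binomial counts with subtype structure, tumor purity and
  heterogeneity, FFPE class-selective enrichment, FF length and 3′
  bias, two sequencing-depth regimes, and storage-age degradation,
  all with exported ground truth so every pipeline stage is testable
  without any external download.
* **One-command orchestration** (`tnbc_concord.cli_report`, console
  script `tnbc-concord`) — simulate → subtype → concordance → DE →
  removal → bias from a single YAML config, with a structured JSON
  report.

## Worked example

```python
from tnbc_concord.cli_report import run_pipeline

report = run_pipeline({"seed": 1, "sim": {"n_pairs": 21}}, output_dir="demo")
```

generates a 21-pair FF/FFPE cohort (5000 genes, 400 centroid genes,
4 subtypes) and runs every stage.  With seed 1 the report contains:

```
subtyping (FF)       distribution {BL1: 0.19, BL2: 0.381, M: 0.095, LAR: 0.333, UNCLASSIFIED: 0.0}
concordance          21/21 identical calls, rate 1.000, exact 95% CI [0.839, 1.000]
de                   167 differential transcripts (148 FFPE-enriched, 19 FF-enriched)
recorrelation        mean paired Spearman rho 0.9549 -> 0.9572 after removal (p < 1e-5)
bias (class totals)  88.6% of differential transcripts FFPE-enriched
exon_bias            mean 3' statistic: FF +0.736 vs FFPE -0.075 over 30 long genes
centroid_reduction   400 -> 396 genes, call agreement 1.00
```

Reading: every FF/FFPE pair got the same subtype call (the exact CI
still spans down to 0.84 with only 21 pairs); the differential
transcripts are overwhelmingly FFPE-enriched non-coding species;
removing them nudges the paired correlations up; poly-A-selected FF
libraries show strong 3′-skewed exon coverage that ribo-depleted FFPE
libraries lack; and dropping the preparation-dependent genes from the
centroids leaves every subtype call unchanged.

The same pipeline runs on real data by replacing the `sim:` section
with a `data:` section pointing at count matrices (merged TSV or a
directory of HTSeq-count files), a gene annotation (TSV or Ensembl
GTF), a centroid TSV, and a pair-design TSV — see the module
docstrings in `tnbc_concord.data_model` for the formats.

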