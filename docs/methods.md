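# Methods

This note documents the models, statistics and numerical choices behind
`tnbc_concord`, and what the synthetic cohorts do and do not establish
about real data.

## Nearest-centroid subtyping

A sample is classified by correlating its expression profile against
per-subtype reference centroids over the intersection of the sample's
genes with the centroid genes.  Counts are FPKM-normalized
(`count · 10⁹ / (length_bp · library_size)`) and transformed to
log2(FPKM + 1) before correlating; the pseudocount keeps zero-count
genes finite.  Spearman rank correlation is the default: it is
invariant under any strictly increasing monotone transform of a
sample's values, which is the property that lets one classifier span
microarray, deep RNA-seq and shallow RNA-seq inputs.  Pearson is
available through `SubtypeCallOptions` for users whose centroids and
samples share a calibrated scale.

Per sample we report the full correlation vector, the call (argmax),
**prediction strength** (the winning ρ) and **prediction confidence**
(ρ₍₁₎ − ρ₍₂₎ ∈ [0, 2]).  Calls with max ρ below `min_strength`
(default 0.1) are UNCLASSIFIED — a deliberate, transparent rule; a
permutation-based significance criterion was considered and rejected
as both slower and harder to reason about across platforms.  Exact
ties in the top correlation are broken lexicographically by subtype
name, so results are deterministic; such calls have confidence 0 and
are low-confidence by construction.  At least
`min_gene_overlap_fraction` (default 0.5) of the centroid genes must
be present in the sample matrix, since platforms measure overlapping
but unequal gene sets.  Zero-variance sample vectors are reported
UNCLASSIFIED with all correlations 0 rather than raising.

Centroid reduction (`reduce_centroids`) drops a supplied gene set
(typically the preparation-dependent transcripts) and refuses to go
below 50 genes by default — below that a rank correlation stops being
a meaningful profile comparison.

## Concordance statistics

A pair of calls is concordant iff identical.  Pairs with an
UNCLASSIFIED member are excluded from the evaluable set by default
(and listed with reasons); a toggle counts them as discordant instead
(two UNCLASSIFIED members then agree).  The concordance rate carries a
two-sided exact Clopper–Pearson interval computed by Beta-quantile
inversion of the binomial tails, with the conventional boundary values
(lower bound 0 at k = 0, upper bound 1 at k = n).  The exact interval
is conservative: empirical coverage in simulation is ≥ the nominal
level, which the test suite checks directly.

The accuracy-vs-confidence curve scores, at each cutoff of a grid
(default 0 to 1, step 0.01), the pairs whose *both* members reach that
confidence — min over the pair members is the conservative
combination — and reports the concordant fraction among them; pair
counts are asserted non-increasing in the cutoff on every run, and
cutoffs retaining zero pairs are reported as undefined rather than
crashing.  `min_confidence_for_accuracy` returns the smallest cutoff
whose accuracy reaches a target (default 0.95) while retaining at
least 5 pairs, so a near-empty stratum cannot declare an operating
point.  The curve is cumulative (≥ cutoff), not binned, which gives a
single crossing of any accuracy target.

Group comparisons of per-pair Spearman correlations use the two-sided
Mann–Whitney U test: the exact null distribution when
min(n₁, n₂) ≤ 8 without ties, otherwise the normal approximation with
tie correction (scipy's implementation behind a thin wrapper).

## Differential-transcript identification

The preparation effect is estimated by an explicit negative-binomial
Wald procedure, written to be fully inspectable:

1. **Size factors** — median-of-ratios: each sample's factor is the
   median over reference genes (genes nonzero in every sample) of the
   ratio of its count to the gene's geometric mean.  If no reference
   gene exists, total-count ratios normalized to geometric mean 1 are
   used with a warning.
2. **Dispersion** — per-gene method of moments,
   α = (s² − μ)/μ², computed within each condition on normalized
   counts, pooled by degrees of freedom, floored at 10⁻⁸.
3. **Effect and test** — log2 FC = log2((μ_FFPE + 0.5)/(μ_FF + 0.5))
   (the 0.5 pseudocount keeps all-zero conditions finite); the delta
   method under NB(μ, α) gives Var(log2 mean) ≈
   (μ + αμ²)/(n (μ + 0.5)² ln²2); the Wald z is referred to the normal
   tail, two-sided.  All-zero genes are flagged with p = 1, FC = 0.
4. **Multiplicity** — Benjamini–Hochberg step-up q-values (an
   order-preserving min-cummin implementation, oracle-tested against
   the literal step-up definition and statsmodels).
5. **Thresholds** — a transcript is differential iff q ≤ 0.05,
   |FC| ≥ 2 and mean normalized count > 4 (all configurable).

No shrinkage of dispersions or fold changes is applied, and pairing is
*not* modeled in the test; with strongly paired data the unpaired Wald
test is conservative (shared tumor variance cancels in the group-mean
difference but still inflates the standard error).  Simulation bears
this out: on independent NB nulls the p ≤ 0.05 fraction is 0.05–0.06,
while on cohorts with strong shared per-pair noise it drops to ~0.02.
Calibration, not agreement with any specific DE package, is the
correctness criterion; planted 4-fold effects are recovered with
> 95% recall at the default thresholds in the acceptance suite.

The removal experiment recomputes per-pair Spearman correlations on
the complement of the differential set (refusing complements under 10
genes) and tests the per-pair deltas with a two-sided Wilcoxon
signed-rank test (not computable for a single pair or all-zero
deltas).

## Bias characterization

* **Class table** — per-class counts of all / differential /
  FFPE-enriched / FF-enriched transcripts over the fixed 15-class
  vocabulary, with percentages of the appropriate denominators
  (differential % of all; enrichment % of differential) and a totals
  row.  The row/column identities are asserted on every invocation.
* **Length bias** — transcript-length summaries for all,
  non-differential, FF-enriched and FFPE-enriched transcripts
  (protein-coding by default) and a Mann–Whitney test on log10 length
  between the two enriched groups; groups under 3 members skip the
  test with a notice.
* **3′ positional bias** — per gene (≥ 4 exons), the Spearman
  correlation between exon index (5′→3′) and mean
  library-size-normalized exon count across a sample group; positive
  means 3′-skewed coverage.  Rank correlation against exon index was
  chosen over curve fitting: it is scale-free (invariant to
  multiplying any sample's counts), needs no model of the decay shape,
  and is testable by construction.
* **Gene-set overrepresentation** — upper-tail hypergeometric
  P(X ≥ k) with the user-supplied universe and GMT collections, BH
  q-values within each collection.  This is overlap
  overrepresentation, not ranked-list enrichment — it matches the
  "k genes overlap, p, q" reporting style and requires no ranking
  choices.
* **Read categories** — on-target/intronic/intergenic percentages use
  *mapped* reads as the denominator; unmapped is reported as a
  percentage of *total* reads.  The two denominators are deliberately
  different and stated here because mixing them silently is a common
  source of irreproducible percentages.
* **rRNA fraction** — counts in rRNA-class genes over total counts per
  sample, the direct readout of ribosomal-depletion efficiency.

## Synthetic cohort generator

The generator is a first-class, tested component that plants every
effect the pipeline is supposed to detect.

**Baseline.** Gene relative abundances are log-normal
(log2 mean 5, sd 3.5).  The heavy tail matters: real libraries spend
most of their depth on the top percentile of genes, which is what
makes median-gene counts limiting at shallow depth.  Counts are
negative binomial via the Gamma–Poisson mixture, with per-gene
dispersions log-uniform in [α/2, 2α] around α = 0.05.

**Subtype structure.** Each of the (default 4) subtypes carries a
Gaussian log2 shift profile over 400 centroid genes (sd 4.5) with
pairwise between-subtype correlation r = 0.6, realized as
√r · common + √(1−r) · own.  Disjoint up-shifted gene blocks
were tried first and rejected: they make the classifier unrealistically
separable (accuracy pinned at 1.0 and confidence compressed below
0.05).  Correlated continuous profiles reproduce what real cohorts
show — every sample correlates substantially with every centroid, and
discrimination rides on the profile differences.  The emitted
centroids are the noiseless expected log2(FPKM+1) class means.

**Tumors.** Each pair (tumor) draws a purity factor uniform in
[0.1, 1] that attenuates its subtype shift, and a tumor-specific log2
expression noise (sd 1.5) *shared* between the FF and FFPE member.
Purity is the planted driver of the confidence–accuracy relation:
low-purity tumors produce low-confidence, error-prone calls, exactly
the stratum a confidence cutoff is supposed to remove.

**Preparation effects.** FFPE (ribo-depleted) libraries multiply
non-poly-A classes up (snoRNA/snRNA/misc RNA/rRNA ×6 down to
processed transcript ×2; protein-coding ×1); FF (poly-A) libraries
retain transcripts with probability exp(−0.08 · length_kb), and
exon-modeled genes additionally weight FF exon coverage by
exp(−0.25 · exons-from-3′-end).  FFPE means get multiplicative
log-normal age noise (ln sd 0.1 for < 4-year-old blocks, 0.5 for
> 10-year-old ones).  The per-gene truth log2 FC is
log2(class multiplier) − log2(FF retention); genes with |truth| ≥ 1
are marked differential with direction.  Note the observed
(normalization-relative) fold change sits ~0.3 log2 units below the
truth value because median-of-ratios anchors to the median
(protein-coding) gene, which itself carries mild FF length loss — the
same compositional effect real pipelines face.

**Depth.** Two regimes with mean total aligned reads 2.4×10⁶
(miseq-like) and 1.45×10⁷ (hiseq-like): the ~6.2× platform ratio at
study scale, multiplied by the 5000/27,577 gene-count ratio so the
default run takes seconds; per-preparation on-target fractions
(FF 0.85, FFPE 0.30) convert aligned depth to gene-level depth, and
the generator also emits per-sample read-category counts
(on-target/intronic/intergenic/unmapped, with elevated unmapped for
old FFPE).  `generate_paired_platform` reuses one structural model
(profiles, purities, tumor and age noise) and resamples counts
independently per regime, so regime contrasts isolate counting noise.

**Determinism.** All randomness derives from the mandatory seed
through named `SeedSequence` children; two runs of the same config are
bit-identical, and the truth tables align one-to-one with the emitted
matrices.

### What the synthetic cohorts do not show

The generator plants clean, known mechanisms; real FFPE data add
cross-linking artifacts, GC and fragment-length effects, batch
structure, intra-tumor sampling differences between the FF and FFPE
blocks, and annotation ambiguity.  Passing the synthetic acceptance
suite demonstrates that the *pipeline* recovers planted structure with
calibrated error rates — not that any particular real cohort will
reach the same accuracy.  Real-data headline numbers (a specific
concordance rate, a specific differential-gene list) depend on
external cohorts and are out of scope of the test suite.

## Experiment sizes and sensitivity designs

Cohort-level tests default to 5000 genes × 21 pairs (seconds per run).
The DE calibration experiments use 2000 genes × 21 pairs per condition
with tumor noise off (independent-sample null, matching the test's
assumptions) and a planted 4× class for recall.  The depth–accuracy
comparison is a sensitivity experiment: a reduced 60-gene panel,
preparation distortions off, tumor noise 0.25 and purities 0.05–0.5
put the classifier near its decision threshold where counting noise —
the only regime-specific term — is visible; with the full study
conditions the shared noise sources (purity, tumor and age noise,
preparation distortions) dominate and mask the depth effect at any
affordable replication.  40 replicates × 32 pairs give the comparison
its precision.

## Known limitations

* The DE test ignores pairing; on strongly paired cohorts it is
  conservative (documented above), and it offers no GLM covariates or
  shrinkage.
* The unclassified rule is a simple strength threshold; services built
  around specific classifiers may use other (unpublished) rules, so
  UNCLASSIFIED fractions are comparable only within this package.
* Gene identifiers are matched as exact trimmed strings — symbol/alias
  mapping is the caller's responsibility.
* The Ensembl biotype → class map covers the common v75 biotypes and
  is overridable; unmapped biotypes are skipped with a warning at GTF
  load.
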