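"""Nearest-centroid molecular subtype classification.

A sample is assigned to the subtype whose reference centroid profile its
expression correlates with most strongly.  Two per-sample quality scores
accompany every call:

* prediction **strength** — the correlation coefficient of the called
  subtype;
* prediction **confidence** — the gap between the highest and
  second-highest subtype correlations, in [0, 2].

Samples whose best correlation falls below ``min_strength`` are reported as
``UNCLASSIFIED``.  Correlations default to Spearman on log2(FPKM+1), which
makes calls invariant to any strictly increasing monotone transform of the
sample vector and therefore robust across expression platforms; Pearson is
available through :class:`SubtypeCallOptions`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tnbc_concord.data_model import CentroidSet, ExpressionMatrix, GeneAnnotation

__all__ = [
    "UNCLASSIFIED",
    "SubtypeCallOptions",
    "SubtypeResult",
    "SubtypeCohortResult",
    "fpkm_normalize",
    "subtype_call",
    "subtype_cohort",
    "reduce_centroids",
    "results_to_frame",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class SubtypeCallOptions:
    """Options controlling the nearest-centroid call.

    correlation_method
        ``spearman`` (default) or ``pearson``.
    min_strength
        Correlation threshold below which the call is ``UNCLASSIFIED``.
    min_gene_overlap_fraction
        Required fraction of centroid genes present in the sample matrix.
    log_transform
        Apply log2(x+1) to FPKM values before correlating; counts/FPKM
        matrices already on a log scale should pass False.
    """

    correlation_method: str = "spearman"
    min_strength: float = 0.1
    min_gene_overlap_fraction: float = 0.5
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError(
                f"correlation_method must be spearman|pearson, got "
                f"{self.correlation_method!r}"
            )
        if not (0.0 <= self.min_strength < 1.0):
            raise ValueError("min_strength must be in [0, 1)")
        if not (0.0 < self.min_gene_overlap_fraction <= 1.0):
            raise ValueError("min_gene_overlap_fraction must be in (0, 1]")


@dataclass
class SubtypeResult:
    """Per-sample classification outcome."""

    sample_id: str
    correlations: dict[str, float]
    call: str
    strength: float
    confidence: float
    n_genes_used: int


@dataclass
class SubtypeCohortResult:
    """Cohort classification: per-sample results plus distribution.

    ``failures`` maps sample id to the error message for samples that could
    not be classified at all (e.g. insufficient centroid-gene overlap);
    they do not enter the distribution.
    """

    results: list[SubtypeResult]
    distribution: pd.Series
    failures: dict[str, str] = field(default_factory=dict)

    def result_for(self, sample_id: str) -> SubtypeResult:
        for r in self.results:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)


def fpkm_normalize(
    counts: ExpressionMatrix, annotation: GeneAnnotation
) -> ExpressionMatrix:
    """FPKM-normalize a count matrix.

    value(g, s) = count(g, s) * 1e9 / (length(g) * total_count(s)),
    i.e. fragments per kilobase of transcript per million mapped reads.
    """
    if counts.value_kind != "count":
        raise ValueError(f"expected a count matrix, got {counts.value_kind}")
    missing = [g for g in counts.gene_ids if g not in annotation.table.index]
    if missing:
        raise ValueError(
            f"{len(missing)} genes lack a transcript_length in the "
            f"annotation: {missing[:10]}"
        )
    lengths = annotation.lengths().reindex(counts.gene_ids).to_numpy(float)
    totals = counts.data.sum(axis=0).to_numpy(float)
    zero_depth = [s for s, t in zip(counts.sample_ids, totals) if t <= 0]
    if zero_depth:
        raise ValueError(f"zero-depth samples: {zero_depth}")
    fpkm = counts.values * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids),
        value_kind="fpkm",
    )


def _prepare_vector(values: pd.Series, value_kind: str, opts: SubtypeCallOptions):
    if opts.log_transform and value_kind in ("count", "fpkm"):
        return np.log2(values.to_numpy(float) + 1.0)
    return values.to_numpy(float)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        rho = stats.spearmanr(x, y).statistic
    else:
        rho = stats.pearsonr(x, y).statistic
    return float(rho)


def subtype_call(
    sample_values: pd.Series,
    centroids: CentroidSet,
    opts: SubtypeCallOptions | None = None,
    *,
    sample_id: str = "",
    value_kind: str = "fpkm",
) -> SubtypeResult:
    """Call the molecular subtype of one sample expression vector.

    Correlations are computed on the intersection of the sample's genes
    with the centroid genes.  A zero-variance sample vector yields
    ``UNCLASSIFIED`` with all correlations 0 and a warning.  Ties in the
    top correlation are broken lexicographically by subtype name (such
    calls have confidence 0 by construction).
    """
    opts = opts or SubtypeCallOptions()
    sample_values = sample_values.dropna()
    shared = [g for g in centroids.gene_ids if g in sample_values.index]
    overlap = len(shared) / centroids.n_genes
    if overlap < opts.min_gene_overlap_fraction:
        raise ValueError(
            f"sample {sample_id or '<unnamed>'}: only {overlap:.1%} of "
            f"centroid genes present "
            f"(minimum {opts.min_gene_overlap_fraction:.1%})"
        )
    x = _prepare_vector(sample_values.loc[shared], value_kind, opts)
    names = centroids.subtype_names
    if np.ptp(x) == 0:
        warnings.warn(
            f"sample {sample_id or '<unnamed>'} has zero variance over "
            "centroid genes; reported UNCLASSIFIED",
            stacklevel=2,
        )
        corr = {k: 0.0 for k in names}
        return SubtypeResult(sample_id, corr, UNCLASSIFIED, 0.0, 0.0, len(shared))
    corr = {
        k: _correlate(x, centroids.data.loc[shared, k].to_numpy(float),
                      opts.correlation_method)
        for k in names
    }
    ranked = sorted(corr, key=lambda k: (-corr[k], k))
    top = ranked[0]
    strength = corr[top]
    confidence = strength - corr[ranked[1]]
    call = top if strength >= opts.min_strength else UNCLASSIFIED
    return SubtypeResult(sample_id, corr, call, strength, confidence, len(shared))


def subtype_cohort(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    opts: SubtypeCallOptions | None = None,
) -> SubtypeCohortResult:
    """Classify every sample of a matrix and tabulate the call distribution.

    Per-sample errors are collected into ``failures`` instead of aborting
    the cohort.  Distribution fractions sum to 1 over classified samples,
    with ``UNCLASSIFIED`` as its own category.
    """
    opts = opts or SubtypeCallOptions()
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    results: list[SubtypeResult] = []
    failures: dict[str, str] = {}
    for s in matrix.sample_ids:
        try:
            results.append(
                subtype_call(
                    matrix.sample(s), centroids, opts,
                    sample_id=s, value_kind=matrix.value_kind,
                )
            )
        except ValueError as exc:  # pragma: no cover - message path
            failures[s] = str(exc)
    categories = centroids.subtype_names + [UNCLASSIFIED]
    counts = pd.Series(0, index=categories, dtype=float)
    for r in results:
        counts[r.call] += 1
    distribution = counts / counts.sum() if counts.sum() else counts
    return SubtypeCohortResult(results, distribution, failures)


def reduce_centroids(
    centroids: CentroidSet,
    exclude_gene_ids,
    min_size: int = 50,
) -> CentroidSet:
    """Drop a set of genes from the centroid profiles.

    This is the gene-set size-reduction step: genes that vary with tissue
    processing or platform are removed so that the remaining signature
    still reproduces the full-centroid calls.  Fails if fewer than
    ``min_size`` genes would remain.
    """
    exclude = {str(g).strip() for g in exclude_gene_ids}
    keep = [g for g in centroids.gene_ids if g not in exclude]
    if len(keep) < min_size:
        raise ValueError(
            f"centroid reduction leaves {len(keep)} genes, below the "
            f"minimum usable size {min_size}"
        )
    return CentroidSet(centroids.data.loc[keep].copy())


def results_to_frame(results: list[SubtypeResult]) -> pd.DataFrame:
    """Flatten SubtypeResults into a table (one row per sample)."""
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        row.update({f"rho_{k}": v for k, v in r.correlations.items()})
        row.update(
            call=r.call,
            strength=r.strength,
            confidence=r.confidence,
            n_genes_used=r.n_genes_used,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
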