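"""Differential-transcript identification between tissue preparations.

A self-contained negative-binomial pipeline for calling transcripts that
differ between FF and FFPE (or between platforms): median-of-ratios library
size factors, method-of-moments gene dispersion pooled within condition, a
Wald test on the log2 fold change with a delta-method standard error,
Benjamini-Hochberg FDR adjustment, and the joint threshold filter
(|FC| >= 2, q <= 0.05, mean normalized count > 4 by default).

Also implements the removal experiment: recompute paired whole-genome
Spearman correlations after dropping the differential transcripts and test
whether the per-pair correlations improved.

This is an explicit, transparent NB Wald procedure; it does not use
shrinkage estimators of dispersion or fold change, and numeric agreement
with any particular DE package is not a goal — calibration is established
by null and planted-signal simulation instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tnbc_concord.data_model import ExpressionMatrix, PairedDesign

__all__ = [
    "DEOptions",
    "size_factors",
    "bh_fdr",
    "nb_wald_test",
    "remove_and_recorrelate",
    "RecorrelationResult",
]


@dataclass
class DEOptions:
    """Thresholds defining a differential transcript.

    ``is_differential`` iff q <= fdr_threshold and
    |log2FC| >= log2(fc_threshold) and base_mean > count_threshold.
    """

    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    count_threshold: float = 4.0
    dispersion_floor: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "fdr_threshold", "count_threshold",
                     "dispersion_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, ExpressionMatrix):
        if counts.value_kind != "count":
            raise ValueError("differential testing expects raw counts")
        return counts.data
    return counts


def size_factors(counts) -> pd.Series:
    """Median-of-ratios library size factors.

    Each sample's factor is the median, over reference genes, of the ratio
    of its count to the gene's geometric mean across samples; genes with a
    zero in any sample are excluded from the reference.  If no gene is
    nonzero everywhere, falls back to total-count ratios (normalized to
    geometric mean 1) with a warning.
    """
    data = _as_frame(counts)
    if data.shape[1] == 0:
        raise ValueError("no samples")
    values = data.to_numpy(float)
    all_nonzero = np.all(values > 0, axis=1)
    if not all_nonzero.any():
        warnings.warn(
            "no gene with nonzero counts in every sample; using "
            "total-count size factors",
            stacklevel=2,
        )
        totals = values.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total count")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=data.columns, name="size_factor")
    ref = values[all_nonzero]
    log_gm = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_gm[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=data.columns, name="size_factor")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j >= p_i of (n * p_j / rank_j), capped at 1;
    the adjustment is order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def nb_wald_test(
    counts,
    condition: pd.Series | dict,
    opts: DEOptions | None = None,
    *,
    reference: str = "FF",
    treatment: str = "FFPE",
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test between two conditions.

    For each gene, normalized counts (median-of-ratios) are summarized per
    condition; the NB dispersion is estimated by method of moments
    ``alpha = (var - mu) / mu^2`` within each condition and pooled by
    degrees of freedom, floored at ``dispersion_floor``.  The log2 fold
    change is ``log2((mean_trt + 0.5) / (mean_ref + 0.5))`` (pseudocount
    keeps all-zero conditions finite), its standard error follows from the
    delta method under NB(mu, alpha), the two-sided p-value from the normal
    tail of the Wald z, and q-values from Benjamini-Hochberg.

    Returns a DataFrame indexed by gene id with columns base_mean,
    log2_fc, p_value, q_value, is_differential, enriched_in, all_zero.
    Genes with all-zero counts are flagged with p = 1 and fold change 0.
    """
    opts = opts or DEOptions()
    data = _as_frame(counts)
    cond = pd.Series(condition).astype(str)
    cond = cond.reindex(data.columns)
    if cond.isna().any():
        missing = list(data.columns[cond.isna()])
        raise ValueError(f"samples without condition label: {missing}")
    levels = {reference, treatment}
    if set(cond.unique()) - levels:
        raise ValueError(
            f"condition labels must be {sorted(levels)}, got "
            f"{sorted(cond.unique())}"
        )
    ref_samples = list(cond.index[cond == reference])
    trt_samples = list(cond.index[cond == treatment])
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("need >=2 samples per condition")

    sf = size_factors(data)
    norm = data.to_numpy(float) / sf.to_numpy()[None, :]
    ref_idx = [data.columns.get_loc(s) for s in ref_samples]
    trt_idx = [data.columns.get_loc(s) for s in trt_samples]
    n1, n2 = len(ref_idx), len(trt_idx)

    mu1 = norm[:, ref_idx].mean(axis=1)
    mu2 = norm[:, trt_idx].mean(axis=1)
    v1 = norm[:, ref_idx].var(axis=1, ddof=1)
    v2 = norm[:, trt_idx].var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(mu1 > 0, (v1 - mu1) / mu1**2, 0.0)
        a2 = np.where(mu2 > 0, (v2 - mu2) / mu2**2, 0.0)
    alpha = ((n1 - 1) * a1 + (n2 - 1) * a2) / (n1 + n2 - 2)
    alpha = np.maximum(alpha, opts.dispersion_floor)

    log2_fc = np.log2((mu2 + 0.5) / (mu1 + 0.5))
    # delta method: Var(log(mean_c + 0.5)) ~ Var(mean_c) / (mean_c + 0.5)^2
    var_mean1 = (mu1 + alpha * mu1**2) / n1
    var_mean2 = (mu2 + alpha * mu2**2) / n2
    var_log2 = (
        var_mean1 / (mu1 + 0.5) ** 2 + var_mean2 / (mu2 + 0.5) ** 2
    ) / np.log(2.0) ** 2
    se = np.sqrt(var_log2)

    all_zero = (mu1 == 0) & (mu2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2_fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    p[all_zero] = 1.0
    log2_fc[all_zero] = 0.0

    q = bh_fdr(p)
    base_mean = norm.mean(axis=1)
    is_diff = (
        (q <= opts.fdr_threshold)
        & (np.abs(log2_fc) >= np.log2(opts.fc_threshold))
        & (base_mean > opts.count_threshold)
    )
    enriched = np.where(
        is_diff & (log2_fc > 0), treatment,
        np.where(is_diff & (log2_fc < 0), reference, "none"),
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
            "is_differential": is_diff,
            "enriched_in": enriched,
            "all_zero": all_zero,
        },
        index=data.index.copy(),
    )


@dataclass
class RecorrelationResult:
    """Per-pair Spearman correlations before/after differential-gene removal."""

    per_pair: pd.DataFrame  # columns rho_all, rho_reduced, delta
    n_removed: int
    n_kept: int
    p_value: float | None  # Wilcoxon signed-rank on deltas; None if n<2

    @property
    def mean_before(self) -> float:
        return float(self.per_pair["rho_all"].mean())

    @property
    def mean_after(self) -> float:
        return float(self.per_pair["rho_reduced"].mean())


def remove_and_recorrelate(
    matrix: ExpressionMatrix,
    de_table: pd.DataFrame,
    design: PairedDesign,
    min_kept: int = 10,
) -> RecorrelationResult:
    """Paired correlations on all genes vs the non-differential complement.

    Removing transcripts that vary with tissue processing should bring the
    two preparations of a specimen closer together; per-pair Spearman
    correlations are computed on the full gene set and on the complement of
    the differential set, and the paired deltas are tested with a
    two-sided Wilcoxon signed-rank test (marked not computable for a
    single pair or all-zero deltas).
    """
    from tnbc_concord.concordance import paired_expression_correlation

    removed = set(de_table.index[de_table["is_differential"]])
    kept = [g for g in matrix.gene_ids if g not in removed]
    if len(kept) < min_kept:
        raise ValueError(
            f"only {len(kept)} genes remain after removal (minimum {min_kept})"
        )
    rho_all = paired_expression_correlation(matrix, design)
    rho_red = paired_expression_correlation(matrix, design, gene_subset=kept)
    per_pair = pd.DataFrame(
        {"rho_all": rho_all, "rho_reduced": rho_red,
         "delta": rho_red - rho_all}
    )
    deltas = per_pair["delta"].dropna().to_numpy()
    p_value: float | None = None
    if deltas.size >= 2 and np.any(deltas != 0):
        p_value = float(stats.wilcoxon(deltas, alternative="two-sided").pvalue)
    return RecorrelationResult(
        per_pair, len(removed & set(matrix.gene_ids)), len(kept), p_value
    )
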