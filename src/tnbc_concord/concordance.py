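"""Paired subtype-call agreement statistics.

Concordance between two preparations (FF vs FFPE) or platforms (microarray
vs RNA-seq, HiSeq vs MiSeq) of the same specimens: the fraction of
evaluable pairs with identical subtype calls, with a two-sided exact
Clopper-Pearson binomial confidence interval; the accuracy-vs-confidence
operating curve and the smallest confidence cutoff achieving a target
accuracy; and paired whole-transcriptome Spearman correlations with a
Mann-Whitney U comparison between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tnbc_concord.data_model import ExpressionMatrix, PairedDesign
from tnbc_concord.subtyping import UNCLASSIFIED, SubtypeResult

__all__ = [
    "ConcordanceReport",
    "ConfidenceAccuracyCurve",
    "MannWhitneyResult",
    "clopper_pearson",
    "concordance",
    "accuracy_vs_confidence",
    "min_confidence_for_accuracy",
    "paired_expression_correlation",
    "compare_groups",
]


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided exact (Clopper-Pearson) binomial confidence interval.

    Inverts the binomial tail sums through Beta quantiles:
    ``low = BetaQ(alpha/2; k, n-k+1)`` (0 when k=0) and
    ``high = BetaQ(1-alpha/2; k+1, n-k)`` (1 when k=n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


@dataclass
class ConcordanceReport:
    """Agreement between paired subtype calls with an exact CI."""

    n_pairs_evaluable: int
    n_concordant: int
    rate: float
    ci_low: float
    ci_high: float
    level: float
    excluded_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        assert self.n_concordant <= self.n_pairs_evaluable
        assert 0.0 <= self.ci_low <= self.rate <= self.ci_high <= 1.0


@dataclass
class ConfidenceAccuracyCurve:
    """Accuracy among pairs whose both members reach a confidence cutoff.

    ``accuracy`` is NaN at cutoffs retaining zero pairs (undefined point).
    """

    cutoffs: np.ndarray
    n_pairs: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.n_pairs) <= 0), "pair counts must be non-increasing"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "n_pairs": self.n_pairs, "accuracy": self.accuracy}
        )


def _as_result_map(results) -> dict[str, SubtypeResult]:
    if isinstance(results, dict):
        return results
    if hasattr(results, "results"):  # SubtypeCohortResult
        results = results.results
    return {r.sample_id: r for r in results}


def _resolve_pairs(results_a, results_b, design: PairedDesign):
    a = _as_result_map(results_a)
    b = _as_result_map(results_b)
    resolved = []
    for pid, sa, sb in design.pairs():
        if sa not in a:
            raise KeyError(f"pair {pid!r}: sample {sa!r} missing from results_a")
        if sb not in b:
            raise KeyError(f"pair {pid!r}: sample {sb!r} missing from results_b")
        resolved.append((pid, a[sa], b[sb]))
    return resolved


def concordance(
    results_a,
    results_b,
    design: PairedDesign,
    exclude_unclassified: bool = True,
    level: float = 0.95,
) -> ConcordanceReport:
    """Subtype-call concordance over the pairs of a design.

    A pair is concordant iff the two calls are identical.  With
    ``exclude_unclassified`` (default), pairs with UNCLASSIFIED on either
    side are excluded from the evaluable set and listed with reasons;
    otherwise they count as discordant unless both members are
    UNCLASSIFIED.
    """
    pairs = _resolve_pairs(results_a, results_b, design)
    excluded: list[tuple[str, str]] = []
    k = 0
    n = 0
    for pid, ra, rb in pairs:
        unclass = [
            s.sample_id for s in (ra, rb) if s.call == UNCLASSIFIED
        ]
        if exclude_unclassified and unclass:
            excluded.append((pid, f"UNCLASSIFIED call: {', '.join(unclass)}"))
            continue
        n += 1
        if ra.call == rb.call:
            k += 1
    if n == 0:
        raise ValueError("no evaluable pairs")
    low, high = clopper_pearson(k, n, level)
    return ConcordanceReport(n, k, k / n, low, high, level, excluded)


def accuracy_vs_confidence(
    results_a,
    results_b,
    design: PairedDesign,
    cutoff_grid=None,
    exclude_unclassified: bool = True,
) -> ConfidenceAccuracyCurve:
    """Concordance as a function of a prediction-confidence cutoff.

    At each cutoff, the evaluable pairs are restricted to those whose
    *both* members have confidence >= cutoff (min of the two confidences is
    the conservative pair score); accuracy is the concordant fraction among
    them.  The default grid is 0 to 1 in steps of 0.01.
    """
    if cutoff_grid is None:
        cutoff_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    cutoffs = np.asarray(cutoff_grid, dtype=float)
    if cutoffs.size == 0:
        raise ValueError("empty cutoff grid")
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoff grid must be strictly increasing")
    if cutoffs[0] < 0 or cutoffs[-1] > 2:
        raise ValueError("cutoffs must lie within [0, 2]")
    pairs = _resolve_pairs(results_a, results_b, design)
    conf = []
    agree = []
    for _, ra, rb in pairs:
        if exclude_unclassified and UNCLASSIFIED in (ra.call, rb.call):
            continue
        conf.append(min(ra.confidence, rb.confidence))
        agree.append(ra.call == rb.call)
    conf_arr = np.asarray(conf, dtype=float)
    agree_arr = np.asarray(agree, dtype=bool)
    n_pairs = np.empty_like(cutoffs, dtype=int)
    accuracy = np.full_like(cutoffs, np.nan, dtype=float)
    for i, c in enumerate(cutoffs):
        mask = conf_arr >= c
        n_pairs[i] = int(mask.sum())
        if n_pairs[i]:
            accuracy[i] = float(agree_arr[mask].mean())
    return ConfidenceAccuracyCurve(cutoffs, n_pairs, accuracy)


def min_confidence_for_accuracy(
    curve: ConfidenceAccuracyCurve,
    target: float = 0.95,
    min_pairs: int = 5,
) -> float | None:
    """Smallest grid cutoff whose accuracy reaches ``target``.

    Cutoffs retaining fewer than ``min_pairs`` pairs are ignored so that a
    near-empty stratum cannot declare an operating point.  Returns None if
    the target is never reached.
    """
    if curve.cutoffs.size == 0:
        raise ValueError("empty curve")
    for c, n, acc in zip(curve.cutoffs, curve.n_pairs, curve.accuracy):
        if n >= min_pairs and not np.isnan(acc) and acc >= target:
            return float(c)
    return None


def paired_expression_correlation(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    gene_subset=None,
) -> pd.Series:
    """Spearman rank correlation for each pair of samples.

    Computed on ``gene_subset`` when given (>=3 shared genes required per
    pair); pairs with a zero-variance member are reported as NaN with a
    warning rather than dropped.
    """
    data = matrix.data
    if gene_subset is not None:
        keep = [g for g in gene_subset if g in data.index]
        data = data.loc[keep]
    rhos = {}
    for pid, sa, sb in design.pairs():
        for s in (sa, sb):
            if s not in data.columns:
                raise KeyError(f"pair {pid!r}: sample {s!r} missing from matrix")
        sub = data[[sa, sb]].dropna()
        if sub.shape[0] < 3:
            raise ValueError(
                f"pair {pid!r}: only {sub.shape[0]} shared genes (need >=3)"
            )
        x = sub[sa].to_numpy(float)
        y = sub[sb].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"pair {pid!r}: zero-variance expression vector; "
                "correlation undefined",
                stacklevel=2,
            )
            rhos[pid] = np.nan
            continue
        rhos[pid] = float(stats.spearmanr(x, y).statistic)
    return pd.Series(rhos, name="spearman_rho")


@dataclass
class MannWhitneyResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def compare_groups(group1, group2) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two correlation groups.

    Uses the exact null distribution when min(n1, n2) <= 8 and there are
    no ties, otherwise the normal approximation with tie correction.
    """
    x = np.asarray([v for v in np.asarray(group1, float) if np.isfinite(v)])
    y = np.asarray([v for v in np.asarray(group2, float) if np.isfinite(v)])
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)
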