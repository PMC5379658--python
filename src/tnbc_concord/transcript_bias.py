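"""What kinds of transcripts differ between preparations.

Given a differential-transcript table and a gene annotation, this module
characterizes the differential set: a per-transcript-class accounting of
how many transcripts are differential and in which preparation they are
enriched; a transcript-length bias test (ribosomal-depleted FFPE libraries
retain long transcripts that poly-A selection under-represents); an
exon-level 3' positional-bias statistic (rank correlation of exon counts
with exon index); gene-set overrepresentation by the upper-tail
hypergeometric test with BH q-values; and read-category / rRNA-fraction
summaries of library composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tnbc_concord.data_model import (
    CLASS_DISPLAY_NAMES,
    TRANSCRIPT_CLASSES,
    ExpressionMatrix,
    GeneAnnotation,
)
from tnbc_concord.concordance import MannWhitneyResult, compare_groups
from tnbc_concord.diffexpr import bh_fdr

__all__ = [
    "class_table",
    "LengthBiasResult",
    "length_bias",
    "exon_position_bias",
    "overlap_enrichment",
    "read_category_summary",
    "rrna_fraction",
]

TOTAL_ROW = "Total"


def class_table(
    de_table: pd.DataFrame,
    annotation: GeneAnnotation,
    *,
    group_a: str = "FFPE",
    group_b: str = "FF",
) -> pd.DataFrame:
    """Per-transcript-class accounting of differential transcripts.

    One row per class in the fixed vocabulary plus a totals row, with
    counts of all transcripts, differential transcripts (% of all), and
    the split of the differential set by enriched preparation (% of
    differential).  Every differential gene must be annotated.
    """
    classes = annotation.classes()
    unannotated = [g for g in de_table.index if g not in classes.index]
    if unannotated:
        raise ValueError(
            f"{len(unannotated)} differential-table genes lack annotation: "
            f"{unannotated[:10]}"
        )
    gene_class = classes.reindex(de_table.index)
    is_diff = de_table["is_differential"].astype(bool)
    enriched = de_table["enriched_in"].astype(str)

    rows = []
    for cls in TRANSCRIPT_CLASSES:
        in_cls = gene_class == cls
        n_all = int(in_cls.sum())
        n_diff = int((in_cls & is_diff).sum())
        n_a = int((in_cls & is_diff & (enriched == group_a)).sum())
        n_b = int((in_cls & is_diff & (enriched == group_b)).sum())
        rows.append((CLASS_DISPLAY_NAMES[cls], n_all, n_diff, n_a, n_b))
    totals = (
        TOTAL_ROW,
        sum(r[1] for r in rows),
        sum(r[2] for r in rows),
        sum(r[3] for r in rows),
        sum(r[4] for r in rows),
    )
    rows.append(totals)

    table = pd.DataFrame(
        rows,
        columns=["transcript_class", "n_all", "n_differential",
                 f"n_{group_a.lower()}_enriched", f"n_{group_b.lower()}_enriched"],
    ).set_index("transcript_class")

    with np.errstate(invalid="ignore", divide="ignore"):
        pct_diff = 100.0 * table["n_differential"] / table["n_all"]
        pct_a = 100.0 * table[f"n_{group_a.lower()}_enriched"] / table["n_differential"]
        pct_b = 100.0 * table[f"n_{group_b.lower()}_enriched"] / table["n_differential"]
    table["pct_differential"] = pct_diff.fillna(0.0)
    table[f"pct_{group_a.lower()}_of_differential"] = pct_a.fillna(0.0)
    table[f"pct_{group_b.lower()}_of_differential"] = pct_b.fillna(0.0)

    # structural identities: the class split of the differential set and the
    # column sums against the totals row must hold on every input
    body = table.drop(index=TOTAL_ROW)
    assert (
        table["n_differential"]
        == table[f"n_{group_a.lower()}_enriched"] + table[f"n_{group_b.lower()}_enriched"]
    ).all()
    for col in table.columns[:4]:
        assert body[col].sum() == table.at[TOTAL_ROW, col]
    return table


@dataclass
class LengthBiasResult:
    """Transcript-length summaries by differential group plus a test."""

    summary: pd.DataFrame  # index: group; columns n, median_bp, mean_bp, ...
    test: MannWhitneyResult | None
    note: str = ""


def length_bias(
    de_table: pd.DataFrame,
    annotation: GeneAnnotation,
    *,
    restrict_class: str | None = "protein_coding",
    group_a: str = "FFPE",
    group_b: str = "FF",
    min_group: int = 3,
) -> LengthBiasResult:
    """Does the differential set skew toward longer transcripts?

    Summarizes transcript length (bp and log10 bp) for all transcripts,
    non-differential transcripts, and the two enriched groups, and runs a
    two-sided Mann-Whitney U test on log10 length between the two enriched
    groups.  By default restricted to protein-coding transcripts.  If
    either enriched group has fewer than ``min_group`` members, summaries
    are still reported and the test is skipped with a notice.
    """
    lengths = annotation.lengths()
    missing = [g for g in de_table.index if g not in lengths.index]
    if missing:
        raise ValueError(f"genes without length annotation: {missing[:10]}")
    sub = de_table.copy()
    sub["length"] = lengths.reindex(sub.index)
    if restrict_class is not None:
        cls = annotation.classes().reindex(sub.index)
        sub = sub[cls == restrict_class]
    is_diff = sub["is_differential"].astype(bool)
    groups = {
        "all": sub,
        "non_differential": sub[~is_diff],
        f"{group_b}_enriched": sub[sub["enriched_in"] == group_b],
        f"{group_a}_enriched": sub[sub["enriched_in"] == group_a],
    }
    summary = pd.DataFrame(
        {
            name: {
                "n": len(g),
                "median_bp": float(g["length"].median()) if len(g) else np.nan,
                "mean_bp": float(g["length"].mean()) if len(g) else np.nan,
                "median_log10": float(np.log10(g["length"]).median()) if len(g) else np.nan,
                "mean_log10": float(np.log10(g["length"]).mean()) if len(g) else np.nan,
            }
            for name, g in groups.items()
        }
    ).T
    a = groups[f"{group_a}_enriched"]["length"].to_numpy(float)
    b = groups[f"{group_b}_enriched"]["length"].to_numpy(float)
    if len(a) < min_group or len(b) < min_group:
        return LengthBiasResult(
            summary, None,
            note=f"test skipped: enriched group below {min_group} transcripts",
        )
    test = compare_groups(np.log10(a), np.log10(b))
    return LengthBiasResult(summary, test)


def exon_position_bias(
    exon_counts: ExpressionMatrix,
    gene_model: dict[str, list[str]],
    sample_groups: dict[str, list[str]],
    min_exons: int = 4,
) -> pd.DataFrame:
    """Per-gene 3' positional-bias statistic per sample group.

    For each gene with >= ``min_exons`` exons, the statistic is the
    Spearman rank correlation between exon index (5'->3') and the mean
    library-size-normalized exon count across the group's samples;
    positive values indicate 3'-biased coverage (the poly-A selection
    signature), negative values 5' bias.  Normalizing each sample by its
    total makes the statistic invariant to scaling any sample's counts.
    Returns a gene-by-group DataFrame; with exactly two groups a
    ``diff_<a>_minus_<b>`` column is appended.  Genes below the exon
    minimum are skipped (count available via the ``attrs['n_skipped']``).
    """
    data = exon_counts.data
    norm = data / data.sum(axis=0)
    stats_rows: dict[str, dict[str, float]] = {}
    n_skipped = 0
    for gene, exon_ids in gene_model.items():
        exon_ids = [e for e in exon_ids if e in norm.index]
        if len(exon_ids) < min_exons:
            n_skipped += 1
            continue
        idx = np.arange(len(exon_ids), dtype=float)
        row = {}
        for group, samples in sample_groups.items():
            samples = [s for s in samples if s in norm.columns]
            if not samples:
                row[group] = np.nan
                continue
            mean_counts = norm.loc[exon_ids, samples].mean(axis=1).to_numpy(float)
            if np.ptp(mean_counts) == 0:
                row[group] = 0.0
            else:
                row[group] = float(stats.spearmanr(idx, mean_counts).statistic)
        stats_rows[gene] = row
    out = pd.DataFrame.from_dict(stats_rows, orient="index")
    out.attrs["n_skipped"] = n_skipped
    names = list(sample_groups)
    if len(names) == 2 and not out.empty:
        out[f"diff_{names[0]}_minus_{names[1]}"] = out[names[0]] - out[names[1]]
    return out


def overlap_enrichment(
    query_genes,
    collections: dict[str, set[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query gene list in gene sets.

    For each named set (intersected with the universe first), the p-value
    is the upper tail P(X >= k) of the hypergeometric distribution with
    population N = |universe|, K = |set|, draws n = |query|; q-values are
    BH-adjusted across the sets of the collection.  Rows sorted by p.
    """
    universe = {str(g) for g in universe}
    query = {str(g) for g in query_genes}
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query gene list")
    stray = query - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query genes outside the universe: "
            f"{sorted(stray)[:10]}"
        )
    if not collections:
        raise ValueError("no gene sets supplied")
    rows = []
    for name, members in collections.items():
        members = set(members) & universe
        k = len(query & members)
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append((name, len(members), k, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap_k", "p_value"]
    ).set_index("set_name")
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    return table.sort_values("p_value")


def read_category_summary(
    category_counts: pd.DataFrame,
    groups: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Library-composition percentages and between-group comparisons.

    ``category_counts`` has one row per sample with columns ``on_target``,
    ``intronic``, ``intergenic`` and ``unmapped``.  On/intronic/intergenic
    are expressed as percentages of *mapped* reads; unmapped as a
    percentage of *total* reads (the two denominators are deliberately
    distinct and stated here once).  With a group label per sample, a
    two-sided Mann-Whitney U compares the groups per category.
    """
    required = ["on_target", "intronic", "intergenic", "unmapped"]
    missing = [c for c in required if c not in category_counts.columns]
    if missing:
        raise ValueError(f"missing read-category columns: {missing}")
    counts = category_counts[required].astype(float)
    if (counts < 0).any().any():
        raise ValueError("read-category counts must be non-negative")
    mapped = counts[["on_target", "intronic", "intergenic"]].sum(axis=1)
    zero = list(counts.index[mapped <= 0])
    if zero:
        raise ValueError(f"samples with zero mapped reads: {zero}")
    total = mapped + counts["unmapped"]
    pct = pd.DataFrame(
        {
            "on_target_pct": 100.0 * counts["on_target"] / mapped,
            "intronic_pct": 100.0 * counts["intronic"] / mapped,
            "intergenic_pct": 100.0 * counts["intergenic"] / mapped,
            "unmapped_pct_of_total": 100.0 * counts["unmapped"] / total,
        }
    )
    if groups is None:
        return pct, None
    labels = pd.Series(groups).reindex(pct.index)
    if labels.isna().any():
        raise ValueError(
            f"samples without group label: {list(pct.index[labels.isna()])}"
        )
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    comp_rows = []
    for col in pct.columns:
        a = pct.loc[labels == names[0], col]
        b = pct.loc[labels == names[1], col]
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
            comp_rows.append((col, np.nan, 1.0, "degenerate"))
            continue
        res = compare_groups(a, b)
        comp_rows.append((col, res.statistic, res.p_value, res.method))
    comparison = pd.DataFrame(
        comp_rows, columns=["category", "statistic", "p_value", "method"]
    ).set_index("category")
    return pct, comparison


def rrna_fraction(counts: ExpressionMatrix, annotation: GeneAnnotation) -> pd.Series:
    """Per-sample fraction of counts falling in rRNA-class genes.

    A direct readout of ribosomal-depletion efficiency: effective
    depletion leaves this fraction near zero.
    """
    classes = annotation.classes()
    uncovered = [g for g in counts.gene_ids if g not in classes.index]
    if uncovered:
        raise ValueError(
            f"genes without class annotation: {uncovered[:10]}"
        )
    is_rrna = classes.reindex(counts.gene_ids) == "rRNA"
    totals = counts.data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(
            f"zero-count samples: {list(totals.index[totals <= 0])}"
        )
    frac = counts.data.loc[is_rrna.to_numpy()].sum(axis=0) / totals
    frac.name = "rrna_fraction"
    return frac
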