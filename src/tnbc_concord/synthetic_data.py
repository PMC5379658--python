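"""Synthetic paired FF/FFPE RNA-seq cohorts with known truth.

The generator emulates the statistical structure of a paired
fresh-frozen / FFPE bulk RNA-seq study of subtype-structured tumors:

* log-normal baseline gene abundances with negative-binomial counts
  (gene-level dispersion, log-uniform spread around a central value);
* molecular subtype structure: each subtype carries a Gaussian log2
  shift profile over the centroid genes (sd ``subtype_effect_size``,
  pairwise correlation ``subtype_profile_correlation`` between subtypes —
  real subtype centroids are strongly mutually correlated, which is what
  makes low-purity samples hard to call); the noiseless class means over
  centroid genes are emitted as the reference
  :class:`~tnbc_concord.data_model.CentroidSet`;
* preparation-specific distortions — FFPE (ribosomal-depleted) libraries
  retain non-poly-A transcript classes (snoRNA, snRNA, misc RNA, ...)
  that poly-A selection removes from FF libraries, modeled as per-class
  FFPE multipliers; FF libraries under-represent long transcripts
  (per-gene retention decaying exponentially in length) and show
  exon-level 3' coverage bias; FFPE age adds multiplicative log-normal
  noise;
* two sequencing-depth regimes (``miseq_like`` / ``hiseq_like``) whose
  total-count means keep the ~6.2x depth ratio of the two platforms,
  scaled to the default gene count so a full pipeline run takes seconds.

Every emitted matrix is accompanied by truth tables (per-sample subtype,
per-gene differential status and direction), so subtype recovery, DE
calibration, bias detection and the removal experiment can all be scored
against ground truth.  Output is a pure function of the config (the seed
is mandatory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tnbc_concord.data_model import (
    AGE_CLASSES,
    TRANSCRIPT_CLASSES,
    CentroidSet,
    ExpressionMatrix,
    GeneAnnotation,
    PairedDesign,
)

__all__ = [
    "DEPTH_REGIMES",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "generate",
    "generate_paired_platform",
]

DEPTH_REGIMES = ("miseq_like", "hiseq_like")

#: Transcript-class mix of a human ribo-depleted annotation (relative
#: frequencies of the 15-class vocabulary at whole-transcriptome scale).
DEFAULT_CLASS_PROPORTIONS = {
    "rRNA": 44 / 27577,
    "misc_RNA": 437 / 27577,
    "snoRNA": 326 / 27577,
    "snRNA": 410 / 27577,
    "sense_intronic": 513 / 27577,
    "three_prime_overlapping_ncRNA": 8 / 27577,
    "miRNA": 232 / 27577,
    "mt_RNA": 10 / 27577,
    "pseudogene": 3661 / 27577,
    "antisense": 2881 / 27577,
    "sense_overlapping": 116 / 27577,
    "lincRNA": 1992 / 27577,
    "processed_transcript": 300 / 27577,
    "polymorphic_pseudogene": 17 / 27577,
    "protein_coding": 16630 / 27577,
}

#: Per-class transcript length distribution, natural-log bp (mean, sd).
#: Protein-coding centers near a few kb; small structural RNAs near 100 bp.
DEFAULT_LENGTH_PARAMS = {
    "rRNA": (4.7, 0.3),
    "misc_RNA": (5.3, 0.6),
    "snoRNA": (4.9, 0.3),
    "snRNA": (5.0, 0.25),
    "sense_intronic": (6.5, 0.7),
    "three_prime_overlapping_ncRNA": (6.5, 0.6),
    "miRNA": (4.4, 0.2),
    "mt_RNA": (6.0, 0.8),
    "pseudogene": (7.0, 0.8),
    "antisense": (7.0, 0.7),
    "sense_overlapping": (7.0, 0.7),
    "lincRNA": (7.3, 0.8),
    "processed_transcript": (7.3, 0.7),
    "polymorphic_pseudogene": (7.8, 0.6),
    "protein_coding": (7.9, 0.75),
}

#: FFPE/FF abundance ratio per class: ribosomal depletion retains
#: non-poly-A species that poly-A selection strips from FF libraries.
DEFAULT_FFPE_CLASS_MULTIPLIERS = {
    "rRNA": 6.0,
    "misc_RNA": 6.0,
    "snoRNA": 6.0,
    "snRNA": 6.0,
    "sense_intronic": 5.0,
    "three_prime_overlapping_ncRNA": 4.0,
    "miRNA": 4.0,
    "mt_RNA": 2.0,
    "pseudogene": 3.0,
    "antisense": 3.0,
    "sense_overlapping": 3.0,
    "lincRNA": 2.5,
    "processed_transcript": 2.0,
    "polymorphic_pseudogene": 1.5,
    "protein_coding": 1.0,
}

#: Mean total counts per regime; ~6.2x apart like the two sequencers'
#: aligned-read totals, scaled to the default 5000-gene transcriptome.
DEFAULT_DEPTH_MEAN = {"miseq_like": 2.4e6, "hiseq_like": 1.45e7}

DEFAULT_AGE_NOISE_SD = {"new_lt4y": 0.1, "old_gt10y": 0.5, "unknown": 0.2}

#: Fraction of aligned reads landing in genes: poly-A-selected FF
#: libraries are mostly on-target, ribo-depleted FFPE libraries lose the
#: majority of reads to intronic/intergenic nascent RNA.
DEFAULT_ON_TARGET = {"FF": 0.85, "FFPE": 0.30}

#: Split of off-target aligned reads into (intronic, intergenic): FFPE
#: off-target mass is dominated by intronic nascent transcripts.
OFF_TARGET_SPLIT = {"FF": (0.8, 0.2), "FFPE": (0.857, 0.143)}

#: Unmapped reads as a fraction of total; storage age degrades FFPE.
UNMAPPED_FRACTION = {"FF": 0.05, "FFPE": 0.06, "FFPE_old": 0.13}

DEFAULT_SUBTYPE_NAMES = ("BL1", "BL2", "M", "LAR")


@dataclass
class SimConfig:
    """Configuration of the paired-cohort generator.

    seed
        Mandatory; all randomness derives from it.
    n_genes, class_proportions, length_params
        Transcriptome size, class mix (must sum to 1) and per-class
        log-normal length parameters (ln bp).
    n_subtypes, subtype_names, n_centroid_genes, subtype_effect_size,
    subtype_profile_correlation
        Subtype structure: per-subtype Gaussian log2 shift profiles over
        the centroid genes with sd ``subtype_effect_size`` and pairwise
        correlation ``subtype_profile_correlation``; discrimination
        scales with effect * sqrt(1 - correlation).
    baseline_log2_mean, baseline_log2_sd
        Log-normal baseline abundance (log2 units); the default sd gives
        the heavy-tailed transcriptome of real libraries, where the top
        percentile of genes absorbs much of the depth and median-gene
        counts become limiting at low depth.
    tumor_noise_sd, purity_range
        Biological heterogeneity: tumor-specific log2 expression noise
        shared between the two preparations of a pair, and a per-tumor
        purity factor (uniform in ``purity_range``) attenuating the
        subtype effect — low-purity tumors yield low-confidence calls.
    n_pairs, age_classes
        Cohort size; optional per-pair age class (default all new).
    depth_mean, depth_cv, on_target_fraction
        Mean total aligned reads per regime, sample-to-sample variation,
        and the per-preparation fraction of those reads that land in
        genes (gene-level depth = depth * on-target fraction).
    nb_dispersion, dispersion_spread
        Central NB dispersion; per-gene values are log-uniform in
        [alpha/spread, alpha*spread].
    ffpe_class_multipliers, ff_length_bias_strength, three_prime_decay_rate
        Preparation distortions: per-class FFPE enrichment, FF retention
        exp(-strength * length_kb), and the per-exon decay of FF coverage
        toward the 5' end of exon-modeled genes.
    age_noise_sd
        Multiplicative log-normal noise (ln units) on FFPE means, by age
        class.
    n_exon_genes
        Number of long protein-coding genes to model at exon level.
    """

    seed: int
    n_genes: int = 5000
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    length_params: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PARAMS)
    )
    n_subtypes: int = 4
    subtype_names: tuple = DEFAULT_SUBTYPE_NAMES
    n_centroid_genes: int = 400
    subtype_effect_size: float = 4.5
    subtype_profile_correlation: float = 0.6
    tumor_noise_sd: float = 1.5
    purity_range: tuple = (0.1, 1.0)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 3.5
    n_pairs: int = 21
    age_classes: tuple | None = None
    depth_mean: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_MEAN))
    depth_cv: float = 0.15
    on_target_fraction: dict = field(default_factory=lambda: dict(DEFAULT_ON_TARGET))
    nb_dispersion: float = 0.05
    dispersion_spread: float = 2.0
    ffpe_class_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_FFPE_CLASS_MULTIPLIERS)
    )
    ff_length_bias_strength: float = 0.08
    three_prime_decay_rate: float = 0.25
    age_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_AGE_NOISE_SD))
    n_exon_genes: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(TRANSCRIPT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in proportions: {sorted(unknown)}")
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if len(self.subtype_names) < self.n_subtypes:
            raise ValueError("not enough subtype_names for n_subtypes")
        if self.n_centroid_genes < self.n_subtypes:
            raise ValueError("n_centroid_genes must cover every subtype")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in ("subtype_effect_size", "tumor_noise_sd", "depth_cv",
                     "ff_length_bias_strength", "three_prime_decay_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be > 0")
        if self.nb_dispersion <= 0 or self.dispersion_spread < 1:
            raise ValueError("nb_dispersion > 0 and dispersion_spread >= 1 required")
        for prep in ("FF", "FFPE"):
            f = self.on_target_fraction.get(prep)
            if f is None or not (0.0 < f <= 1.0):
                raise ValueError(
                    f"on_target_fraction[{prep!r}] must be in (0, 1]")
        if not (0.0 <= self.subtype_profile_correlation < 1.0):
            raise ValueError("subtype_profile_correlation must be in [0, 1)")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
        if any(sd < 0 for sd in self.age_noise_sd.values()):
            raise ValueError("age_noise_sd values must be >= 0")
        if self.age_classes is not None:
            if len(self.age_classes) != self.n_pairs:
                raise ValueError("age_classes must have one entry per pair")
            bad = set(self.age_classes) - set(AGE_CLASSES)
            if bad:
                raise ValueError(f"unknown age classes: {sorted(bad)}")
        missing = set(TRANSCRIPT_CLASSES) - set(self.length_params)
        if missing & set(self.class_proportions):
            raise ValueError(f"length_params missing classes: {sorted(missing)}")


@dataclass
class SimTruth:
    """Ground truth aligned one-to-one with the emitted matrices."""

    sample_subtype: pd.Series  # sample id -> true subtype
    pair_subtype: pd.Series  # pair id -> true subtype
    gene_truth: pd.DataFrame  # per gene: class, length, true_log2_fc, ...


@dataclass
class SimResult:
    """One simulated paired cohort at a single depth regime."""

    counts_ff: ExpressionMatrix
    counts_ffpe: ExpressionMatrix
    exon_counts: ExpressionMatrix | None
    gene_model: dict[str, list[str]]
    annotation: GeneAnnotation
    centroids: CentroidSet
    design: PairedDesign
    truth: SimTruth
    regime: str
    read_categories: pd.DataFrame | None = None

    def combined_counts(self) -> tuple[ExpressionMatrix, pd.Series]:
        """FF and FFPE columns side by side, plus a condition label per
        sample (for the differential test)."""
        data = pd.concat([self.counts_ff.data, self.counts_ffpe.data], axis=1)
        labels = pd.Series(
            ["FF"] * self.counts_ff.shape[1] + ["FFPE"] * self.counts_ffpe.shape[1],
            index=data.columns,
        )
        return ExpressionMatrix(data, "count"), labels


class _Model:
    """Deterministic structural model shared across depth regimes."""

    __slots__ = (
        "config", "gene_ids", "classes", "lengths", "base_log2",
        "alpha", "subtype_delta", "centroid_genes", "ff_retention",
        "exon_genes", "exon_lengths", "exon_ff_weights", "pair_subtypes",
        "age_classes", "tumor_noise", "age_noise", "purity", "true_log2_fc",
    )

    def __init__(self, config: SimConfig):
        self.config = config


def _deterministic_class_counts(n: int, proportions: dict) -> dict[str, int]:
    # largest-remainder rounding: reproducible class counts that always
    # include at least one gene of every nonzero-proportion class
    items = [(c, p * n) for c, p in proportions.items() if p > 0]
    counts = {c: int(np.floor(x)) for c, x in items}
    for c, _ in items:
        if counts[c] == 0:
            counts[c] = 1
    short = n - sum(counts.values())
    remainders = sorted(
        items, key=lambda cx: (cx[1] - np.floor(cx[1])), reverse=True
    )
    i = 0
    while short != 0 and remainders:
        c = remainders[i % len(remainders)][0]
        if short > 0:
            counts[c] += 1
            short -= 1
        elif counts[c] > 1:
            counts[c] -= 1
            short += 1
        i += 1
    return counts


def _build_model(config: SimConfig) -> _Model:
    ss = np.random.SeedSequence([int(config.seed), 0x5731])
    rng = np.random.default_rng(ss)
    m = _Model(config)

    n = config.n_genes
    m.gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    class_counts = _deterministic_class_counts(n, config.class_proportions)
    classes = np.concatenate(
        [np.repeat(c, k) for c, k in class_counts.items()]
    )
    rng.shuffle(classes)
    m.classes = classes

    mus = np.array([config.length_params[c][0] for c in classes])
    sds = np.array([config.length_params[c][1] for c in classes])
    m.lengths = np.maximum(
        50, np.round(np.exp(rng.normal(mus, sds)))
    ).astype(int)

    m.base_log2 = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n
    )
    m.alpha = config.nb_dispersion * config.dispersion_spread ** rng.uniform(
        -1.0, 1.0, size=n
    )

    # centroid gene blocks: mostly protein-coding, with a minority of other
    # classes so that preparation distortions touch the signature too
    pc = np.flatnonzero(classes == "protein_coding")
    other = np.flatnonzero(classes != "protein_coding")
    n_cent = min(config.n_centroid_genes, n)
    n_other = min(int(round(0.25 * n_cent)), other.size)
    n_pc = min(n_cent - n_other, pc.size)
    chosen = np.concatenate([
        rng.choice(pc, size=n_pc, replace=False),
        rng.choice(other, size=n_other, replace=False),
    ])
    m.centroid_genes = np.sort(chosen)

    # per-subtype log2 shift profiles over the centroid genes: correlated
    # Gaussians delta_k = e * (sqrt(r) * common + sqrt(1-r) * own)
    e = config.subtype_effect_size
    r = config.subtype_profile_correlation
    common = rng.normal(0.0, 1.0, size=m.centroid_genes.size)
    m.subtype_delta = np.zeros((config.n_subtypes, n))
    for k in range(config.n_subtypes):
        own = rng.normal(0.0, 1.0, size=m.centroid_genes.size)
        m.subtype_delta[k, m.centroid_genes] = e * (
            np.sqrt(r) * common + np.sqrt(1.0 - r) * own
        )

    # FF poly-A retention decays with transcript length
    m.ff_retention = np.exp(
        -config.ff_length_bias_strength * m.lengths / 1000.0
    )

    # exon-level model for a subset of long protein-coding genes
    long_pc = np.flatnonzero((classes == "protein_coding") & (m.lengths >= 2000))
    n_exon = min(config.n_exon_genes, long_pc.size)
    exon_idx = rng.choice(long_pc, size=n_exon, replace=False)
    m.exon_genes = np.sort(exon_idx)
    m.exon_lengths = {}
    m.exon_ff_weights = {}
    for gi in m.exon_genes:
        n_ex = int(rng.integers(8, 19))
        parts = rng.dirichlet(np.full(n_ex, 2.0)) * m.lengths[gi]
        ex_len = np.maximum(1, np.round(parts)).astype(int)
        ex_len[-1] += m.lengths[gi] - ex_len.sum()
        if ex_len[-1] < 1:  # re-balance a pathological rounding
            ex_len = np.full(n_ex, m.lengths[gi] // n_ex, dtype=int)
            ex_len[-1] += m.lengths[gi] - ex_len.sum()
        m.exon_lengths[gi] = ex_len
        # FF coverage decays toward the 5' end (exon 0): weight 1 at 3'
        pos = np.arange(n_ex)
        m.exon_ff_weights[gi] = np.exp(
            -config.three_prime_decay_rate * (n_ex - 1 - pos)
        )

    # FF gene-level retention for exon-modeled genes additionally folds in
    # the length-weighted mean of the 3' exon weights
    for gi in m.exon_genes:
        w = m.exon_ff_weights[gi]
        lw = m.exon_lengths[gi]
        m.ff_retention[gi] *= float((w * lw).sum() / lw.sum())

    subtype_pool = list(config.subtype_names[: config.n_subtypes])
    m.pair_subtypes = [
        subtype_pool[int(i)]
        for i in rng.integers(0, config.n_subtypes, size=config.n_pairs)
    ]
    m.age_classes = (
        list(config.age_classes)
        if config.age_classes is not None
        else ["new_lt4y"] * config.n_pairs
    )

    m.purity = rng.uniform(
        config.purity_range[0], config.purity_range[1], size=config.n_pairs
    )
    # tumor-specific expression (biological heterogeneity): shared between
    # the FF and FFPE member of a pair and across depth regimes, log2 units
    m.tumor_noise = rng.normal(
        0.0, config.tumor_noise_sd, size=(config.n_pairs, n)
    )
    # FFPE storage-age degradation: multiplicative log-normal noise on the
    # FFPE means only, independent of the FF member (ln units, mean 1)
    m.age_noise = np.ones((config.n_pairs, n))
    for j, age in enumerate(m.age_classes):
        sd = float(config.age_noise_sd.get(age, 0.0))
        if sd > 0:
            m.age_noise[j] = np.exp(rng.normal(-sd**2 / 2, sd, size=n))

    mult = np.array(
        [config.ffpe_class_multipliers.get(c, 1.0) for c in classes]
    )
    m.true_log2_fc = np.log2(mult) - np.log2(m.ff_retention)
    return m


def _subtype_shift(m: _Model, subtype: str) -> np.ndarray:
    """Per-gene log2 shift profile for samples of a subtype."""
    k = list(m.config.subtype_names).index(subtype)
    return m.subtype_delta[k]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray):
    """Gamma-Poisson draw of NB(mu, alpha) counts (alpha = dispersion)."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam).astype(float)


def _make_centroids(m: _Model) -> CentroidSet:
    cfg = m.config
    genes = [m.gene_ids[i] for i in m.centroid_genes]
    cols = {}
    for k, name in enumerate(cfg.subtype_names[: cfg.n_subtypes]):
        rel = 2.0 ** (m.base_log2 + _subtype_shift(m, name))
        fpkm = rel / rel.sum() * 1e9 / m.lengths
        cols[name] = np.log2(fpkm[m.centroid_genes] + 1.0)
    return CentroidSet(pd.DataFrame(cols, index=genes))


def _make_annotation(m: _Model) -> GeneAnnotation:
    exon_lengths = [None] * m.config.n_genes
    for gi in m.exon_genes:
        exon_lengths[gi] = tuple(int(x) for x in m.exon_lengths[gi])
    table = pd.DataFrame(
        {
            "transcript_class": m.classes,
            "transcript_length": m.lengths,
            "exon_lengths": exon_lengths,
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )
    return GeneAnnotation(table)


def _sample_regime(m: _Model, regime: str, seed_entropy: int) -> SimResult:
    cfg = m.config
    if regime not in cfg.depth_mean:
        raise ValueError(
            f"regime {regime!r} not configured; have {sorted(cfg.depth_mean)}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 0x9E37, seed_entropy])
    )
    depth_mu = float(cfg.depth_mean[regime])
    sigma = np.sqrt(np.log1p(cfg.depth_cv**2))

    pair_ids = [f"P{i + 1:02d}" for i in range(cfg.n_pairs)]
    ff_ids = [f"{p}_FF" for p in pair_ids]
    ffpe_ids = [f"{p}_FFPE" for p in pair_ids]

    mult = np.array(
        [cfg.ffpe_class_multipliers.get(c, 1.0) for c in m.classes]
    )
    ff_counts = np.empty((cfg.n_genes, cfg.n_pairs))
    ffpe_counts = np.empty((cfg.n_genes, cfg.n_pairs))
    aligned_depth = {}
    exon_cols: dict[str, np.ndarray] = {}
    exon_ids: list[str] = []
    gene_model: dict[str, list[str]] = {}
    for gi in m.exon_genes:
        ids = [f"{m.gene_ids[gi]}:exon{j + 1:02d}"
               for j in range(len(m.exon_lengths[gi]))]
        gene_model[m.gene_ids[gi]] = ids
        exon_ids.extend(ids)

    for j, pid in enumerate(pair_ids):
        shift = m.purity[j] * _subtype_shift(m, m.pair_subtypes[j])
        base_rel = 2.0 ** (m.base_log2 + shift + m.tumor_noise[j])

        ff_rel = base_rel * m.ff_retention
        total_ff = depth_mu * np.exp(rng.normal(-sigma**2 / 2, sigma))
        aligned_depth[f"{pid}_FF"] = total_ff
        depth_ff = total_ff * cfg.on_target_fraction["FF"]
        mu_ff = ff_rel / ff_rel.sum() * depth_ff
        ff_counts[:, j] = _nb_draw(rng, mu_ff, m.alpha)

        ffpe_rel = base_rel * mult * m.age_noise[j]
        total_ffpe = depth_mu * np.exp(rng.normal(-sigma**2 / 2, sigma))
        aligned_depth[f"{pid}_FFPE"] = total_ffpe
        depth_ffpe = total_ffpe * cfg.on_target_fraction["FFPE"]
        mu_ffpe = ffpe_rel / ffpe_rel.sum() * depth_ffpe
        ffpe_counts[:, j] = _nb_draw(rng, mu_ffpe, m.alpha)

        # exon-level counts: gene-level mean split over exons by exon
        # length, with the FF split additionally 3'-weighted
        for gi in m.exon_genes:
            lw = m.exon_lengths[gi].astype(float)
            w_ff = lw * m.exon_ff_weights[gi]
            # mu_ff already carries the aggregate 3' retention; undo it so
            # the exon split reallocates rather than double-counts
            gene_mu_ff = mu_ff[gi] / max(
                (m.exon_ff_weights[gi] * lw).sum() / lw.sum(), 1e-12
            )
            ex_mu_ff = gene_mu_ff * w_ff / lw.sum()
            ex_mu_ffpe = mu_ffpe[gi] * lw / lw.sum()
            a = np.full(len(lw), m.alpha[gi])
            key_ff = f"{pid}_FF"
            key_ffpe = f"{pid}_FFPE"
            exon_cols.setdefault(key_ff, np.empty(0))
            exon_cols.setdefault(key_ffpe, np.empty(0))
            exon_cols[key_ff] = np.concatenate(
                [exon_cols[key_ff], _nb_draw(rng, ex_mu_ff, a)]
            )
            exon_cols[key_ffpe] = np.concatenate(
                [exon_cols[key_ffpe], _nb_draw(rng, ex_mu_ffpe, a)]
            )

    # per-sample read-category accounting: observed gene counts are the
    # on-target reads; off-target aligned mass splits into intronic /
    # intergenic per preparation; unmapped reads scale with total and,
    # for FFPE, with storage age
    cat_rows = {}
    for j, pid in enumerate(pair_ids):
        for prep, col in (("FF", ff_counts[:, j]), ("FFPE", ffpe_counts[:, j])):
            sid = f"{pid}_{prep}"
            on = float(col.sum())
            off = max(aligned_depth[sid] - on, 0.0)
            f_in, f_ig = OFF_TARGET_SPLIT[prep]
            unm_key = (
                "FFPE_old"
                if prep == "FFPE" and m.age_classes[j] == "old_gt10y"
                else prep
            )
            unm_frac = UNMAPPED_FRACTION[unm_key]
            total = aligned_depth[sid] / (1.0 - unm_frac)
            cat_rows[sid] = {
                "on_target": on,
                "intronic": float(rng.poisson(off * f_in)),
                "intergenic": float(rng.poisson(off * f_ig)),
                "unmapped": float(rng.poisson(total * unm_frac)),
            }
    read_categories = pd.DataFrame.from_dict(cat_rows, orient="index")

    counts_ff = ExpressionMatrix(
        pd.DataFrame(ff_counts, index=m.gene_ids, columns=ff_ids), "count"
    )
    counts_ffpe = ExpressionMatrix(
        pd.DataFrame(ffpe_counts, index=m.gene_ids, columns=ffpe_ids), "count"
    )
    exon_counts = None
    if exon_ids:
        exon_counts = ExpressionMatrix(
            pd.DataFrame(exon_cols, index=exon_ids), "count"
        )

    design = PairedDesign(
        pd.DataFrame(
            {
                "sample_a": ff_ids,
                "sample_b": ffpe_ids,
                "platform": regime,
                "age_class": m.age_classes,
            },
            index=pd.Index(pair_ids, name="pair_id"),
        )
    )

    is_centroid = np.zeros(cfg.n_genes, dtype=bool)
    is_centroid[m.centroid_genes] = True
    is_diff = np.abs(m.true_log2_fc) >= 1.0
    gene_truth = pd.DataFrame(
        {
            "transcript_class": m.classes,
            "transcript_length": m.lengths,
            "true_log2_fc": m.true_log2_fc,
            "is_differential": is_diff,
            "enriched_in": np.where(
                is_diff & (m.true_log2_fc > 0), "FFPE",
                np.where(is_diff & (m.true_log2_fc < 0), "FF", "none"),
            ),
            "is_centroid_gene": is_centroid,
            "nb_dispersion": m.alpha,
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )
    sample_subtype = pd.Series(
        {**{s: t for s, t in zip(ff_ids, m.pair_subtypes)},
         **{s: t for s, t in zip(ffpe_ids, m.pair_subtypes)}},
        name="true_subtype",
    )
    pair_subtype = pd.Series(
        dict(zip(pair_ids, m.pair_subtypes)), name="true_subtype"
    )
    pair_subtype = pair_subtype.to_frame()
    pair_subtype["purity"] = m.purity
    pair_subtype = pair_subtype["true_subtype"]
    truth = SimTruth(sample_subtype, pair_subtype, gene_truth)
    return SimResult(
        counts_ff, counts_ffpe, exon_counts, gene_model,
        _make_annotation(m), _make_centroids(m), design, truth, regime,
        read_categories,
    )


_REGIME_ENTROPY = {"miseq_like": 11, "hiseq_like": 12}


def generate(config: SimConfig, regime: str = "hiseq_like") -> SimResult:
    """Generate one paired FF/FFPE cohort at a single depth regime."""
    model = _build_model(config)
    return _sample_regime(model, regime, _REGIME_ENTROPY.get(regime, 13))


def generate_paired_platform(config: SimConfig) -> dict[str, SimResult]:
    """Emit the same cohort (identical underlying means, annotation,
    centroids and truth) at both depth regimes with independent NB
    sampling at each depth."""
    for regime in DEPTH_REGIMES:
        if regime not in config.depth_mean:
            raise ValueError(f"depth regime {regime!r} not configured")
    model = _build_model(config)
    return {
        regime: _sample_regime(model, regime, _REGIME_ENTROPY[regime])
        for regime in DEPTH_REGIMES
    }
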