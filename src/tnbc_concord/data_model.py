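"""Core data containers and TSV readers/writers.

All downstream modules consume only the types defined here: a dense
gene-by-sample :class:`ExpressionMatrix`, a per-gene :class:`GeneAnnotation`
table (transcript class, length, optional ordered exon lengths), a
gene-by-subtype :class:`CentroidSet` defining the nearest-centroid
classifier, and a :class:`PairedDesign` table pairing the two preparations
(or platforms) of each specimen.

Gene identifiers are matched as exact strings after whitespace trimming; no
symbol or alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRANSCRIPT_CLASSES",
    "CLASS_DISPLAY_NAMES",
    "DEFAULT_BIOTYPE_MAP",
    "VALUE_KINDS",
    "AGE_CLASSES",
    "ExpressionMatrix",
    "GeneAnnotation",
    "CentroidSet",
    "PairedDesign",
    "read_expression",
    "read_annotation",
    "read_centroids",
    "read_design",
    "write_expression",
    "write_annotation",
    "write_centroids",
    "write_design",
    "annotation_from_gtf",
    "read_gmt",
]

VALUE_KINDS = ("count", "fpkm", "log_fpkm")

AGE_CLASSES = ("new_lt4y", "old_gt10y", "unknown")

#: Fixed transcript-class vocabulary (canonical tokens).
TRANSCRIPT_CLASSES = (
    "rRNA",
    "misc_RNA",
    "snoRNA",
    "snRNA",
    "sense_intronic",
    "three_prime_overlapping_ncRNA",
    "miRNA",
    "mt_RNA",
    "pseudogene",
    "antisense",
    "sense_overlapping",
    "lincRNA",
    "processed_transcript",
    "polymorphic_pseudogene",
    "protein_coding",
)

#: Human-readable display names for report tables.
CLASS_DISPLAY_NAMES = {
    "rRNA": "rRNA",
    "misc_RNA": "Misc RNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "sense_intronic": "Sense intronic",
    "three_prime_overlapping_ncRNA": "3' overlapping ncRNA",
    "miRNA": "miRNA",
    "mt_RNA": "mt RNA",
    "pseudogene": "Pseudogene",
    "antisense": "Antisense",
    "sense_overlapping": "Sense overlapping",
    "lincRNA": "lincRNA",
    "processed_transcript": "Processed transcript",
    "polymorphic_pseudogene": "Polymorphic pseudogene",
    "protein_coding": "Protein coding",
}

# Accept display names and a few common spelling variants at load time.
_CLASS_ALIASES: dict[str, str] = {}
for _tok, _disp in CLASS_DISPLAY_NAMES.items():
    _CLASS_ALIASES[_tok.lower()] = _tok
    _CLASS_ALIASES[_disp.lower()] = _tok
    _CLASS_ALIASES[_disp.lower().replace(" ", "_")] = _tok
_CLASS_ALIASES["3prime_overlapping_ncrna"] = "three_prime_overlapping_ncRNA"
_CLASS_ALIASES["misc rna"] = "misc_RNA"
_CLASS_ALIASES["mt rna"] = "mt_RNA"

#: Default Ensembl gene_biotype -> transcript class map (overridable at the
#: GTF loading call site).  Pseudogene sub-biotypes collapse onto
#: ``pseudogene``; mitochondrial rRNA/tRNA collapse onto ``mt_RNA``.
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "translated_processed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "IG_C_pseudogene": "pseudogene",
    "IG_J_pseudogene": "pseudogene",
    "IG_V_pseudogene": "pseudogene",
    "TR_J_pseudogene": "pseudogene",
    "TR_V_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "polymorphic_pseudogene",
    "antisense": "antisense",
    "lincRNA": "lincRNA",
    "processed_transcript": "processed_transcript",
    "sense_intronic": "sense_intronic",
    "sense_overlapping": "sense_overlapping",
    "3prime_overlapping_ncrna": "three_prime_overlapping_ncRNA",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "misc_RNA": "misc_RNA",
    "Mt_rRNA": "mt_RNA",
    "Mt_tRNA": "mt_RNA",
}

def normalize_class(label: str) -> str:
    """Map a transcript-class label (token or display form) to its token.

    Raises ``ValueError`` for labels outside the fixed vocabulary.
    """
    key = str(label).strip().lower()
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown transcript class {label!r}; expected one of "
            f"{', '.join(TRANSCRIPT_CLASSES)}"
        ) from None


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Dense gene-by-sample numeric matrix tagged with a value kind.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample-id columns.
    value_kind
        One of ``count``, ``fpkm``, ``log_fpkm``.  Counts must be
        non-negative; FPKM-derived values must be finite.
    """

    data: pd.DataFrame
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind {self.value_kind!r} not in {VALUE_KINDS}"
            )
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str).str.strip()
        _check_unique(list(self.data.index), "gene id")
        _check_unique(list(self.data.columns), "sample id")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.value_kind == "count":
            if values.size and np.nanmin(values) < 0:
                raise ValueError("counts must be non-negative")
        else:
            if values.size and not np.all(np.isfinite(values)):
                raise ValueError(f"{self.value_kind} values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> pd.Series:
        """Expression vector over genes for one sample."""
        return self.data[sample_id]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in gene_ids if g in self.data.index]
        return ExpressionMatrix(self.data.loc[keep].copy(), self.value_kind)


@dataclass
class GeneAnnotation:
    """Per-gene transcript class, length (bp) and optional exon lengths.

    The underlying ``table`` is indexed by gene id with columns
    ``transcript_class``, ``transcript_length`` and ``exon_lengths`` (tuple
    of 5'->3' exon lengths, or None).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"transcript_class", "transcript_length"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        t.index = t.index.astype(str).str.strip()
        _check_unique(list(t.index), "gene id")
        t["transcript_class"] = [normalize_class(c) for c in t["transcript_class"]]
        lengths = pd.to_numeric(t["transcript_length"], errors="raise")
        if (lengths <= 0).any():
            bad = list(t.index[lengths <= 0])
            raise ValueError(f"non-positive transcript_length for genes {bad[:5]}")
        t["transcript_length"] = lengths.astype(int)
        if "exon_lengths" not in t.columns:
            t["exon_lengths"] = None
        checked = []
        for gene, exons in t["exon_lengths"].items():
            if exons is None or (isinstance(exons, float) and np.isnan(exons)):
                checked.append(None)
                continue
            if isinstance(exons, str):
                exons = tuple(int(x) for x in exons.split(",") if x.strip())
            else:
                exons = tuple(int(x) for x in exons)
            if sum(exons) != t.at[gene, "transcript_length"]:
                raise ValueError(
                    f"gene {gene!r}: sum(exon_lengths)={sum(exons)} != "
                    f"transcript_length={t.at[gene, 'transcript_length']}"
                )
            checked.append(exons)
        t["exon_lengths"] = checked

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def lengths(self) -> pd.Series:
        return self.table["transcript_length"]

    def classes(self) -> pd.Series:
        return self.table["transcript_class"]

    def exon_lengths(self, gene_id: str):
        return self.table.at[gene_id, "exon_lengths"]

    def genes_of_class(self, transcript_class: str) -> list[str]:
        tok = normalize_class(transcript_class)
        return list(self.table.index[self.table["transcript_class"] == tok])


@dataclass
class CentroidSet:
    """Gene-by-subtype reference profiles defining the classifier."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str).str.strip()
        _check_unique(list(self.data.index), "centroid gene id")
        _check_unique(list(self.data.columns), "subtype name")
        if self.data.shape[1] < 2:
            raise ValueError(
                f"centroid set needs >=2 subtypes, got {self.data.shape[1]}"
            )
        if self.data.shape[0] < 2:
            raise ValueError(
                f"centroid set needs >=2 genes, got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("centroid values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]


@dataclass
class PairedDesign:
    """Pairing of two preparations/platforms of the same specimens.

    ``table`` is indexed by pair id with columns ``sample_a`` (FF or
    microarray), ``sample_b`` (FFPE or RNA-seq), ``platform`` (free text)
    and ``age_class``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_a", "sample_b"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        t.index = t.index.astype(str).str.strip()
        _check_unique(list(t.index), "pair id")
        for col in ("sample_a", "sample_b"):
            t[col] = t[col].astype(str).str.strip()
        same = t["sample_a"] == t["sample_b"]
        if same.any():
            raise ValueError(
                f"pairs {list(t.index[same])} pair a sample with itself"
            )
        if "platform" not in t.columns:
            t["platform"] = ""
        if "age_class" not in t.columns:
            t["age_class"] = "unknown"
        bad_age = ~t["age_class"].isin(AGE_CLASSES)
        if bad_age.any():
            raise ValueError(
                f"age_class must be one of {AGE_CLASSES}; bad pairs: "
                f"{list(t.index[bad_age])}"
            )

    @property
    def pair_ids(self) -> list[str]:
        return list(self.table.index)

    def pairs(self) -> list[tuple[str, str, str]]:
        """(pair_id, sample_a, sample_b) triples in table order."""
        return [
            (pid, row["sample_a"], row["sample_b"])
            for pid, row in self.table.iterrows()
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: Path) -> pd.DataFrame:
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: file is empty")
    return pd.read_csv(path, sep="\t", dtype=str)


def read_expression(path, value_kind: str = "count") -> ExpressionMatrix:
    """Read a merged gene-by-sample TSV, or a directory of per-sample
    HTSeq-count two-column files.

    Merged-file format: first column gene id, header row of sample ids.
    Per-sample format: no header, ``gene<TAB>count``; the sample id is the
    file stem.  Genes present in only some per-sample files are filled with
    0 and a warning is emitted.  HTSeq summary rows (``__no_feature`` etc.)
    are stripped and reported.
    """
    path = Path(path)
    if path.is_dir():
        return _read_htseq_dir(path, value_kind)
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str).str.strip()
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id {dup.iloc[0]!r} in {path}")
    body = raw.drop(columns=[gene_col])
    numeric = pd.DataFrame(index=genes.to_numpy())
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            row = genes[bad].iloc[0]
            raise ValueError(
                f"non-numeric value {body[col][bad].iloc[0]!r} at gene "
                f"{row!r}, sample {col!r} in {path}"
            )
        numeric[col] = converted.to_numpy()
    numeric = _strip_htseq_rows(numeric)
    return ExpressionMatrix(numeric, value_kind)


def _strip_htseq_rows(df: pd.DataFrame) -> pd.DataFrame:
    special = [g for g in df.index if str(g).startswith("__")]
    if special:
        warnings.warn(
            f"stripped {len(special)} HTSeq summary rows: {sorted(special)}",
            stacklevel=3,
        )
        df = df.drop(index=special)
    return df


def _read_htseq_dir(path: Path, value_kind: str) -> ExpressionMatrix:
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"{path}: directory contains no count files")
    columns = {}
    for f in files:
        tab = pd.read_csv(f, sep="\t", header=None, dtype=str)
        if tab.shape[1] != 2:
            raise ValueError(f"{f}: expected two columns, got {tab.shape[1]}")
        genes = tab[0].astype(str).str.strip()
        dup = genes[genes.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene id {dup.iloc[0]!r} in {f}")
        counts = pd.to_numeric(tab[1], errors="coerce")
        if counts.isna().any():
            bad = genes[counts.isna()].iloc[0]
            raise ValueError(f"non-numeric value at gene {bad!r} in {f}")
        columns[f.stem] = pd.Series(counts.to_numpy(), index=genes.to_numpy())
    merged = pd.DataFrame(columns)
    if merged.isna().any().any():
        missing = merged.isna().sum().sum()
        warnings.warn(
            f"{int(missing)} gene/sample cells absent from some per-sample "
            "files; filled with 0",
            stacklevel=3,
        )
        merged = merged.fillna(0.0)
    merged = _strip_htseq_rows(merged)
    return ExpressionMatrix(merged, value_kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path) -> GeneAnnotation:
    """Read a TSV with columns gene_id, transcript_class, transcript_length
    and optional exon_lengths (comma-separated bp, 5'->3')."""
    path = Path(path)
    raw = _read_tsv(path)
    for col in ("gene_id", "transcript_class", "transcript_length"):
        if col not in raw.columns:
            raise ValueError(f"{path}: annotation missing column {col!r}")
    raw = raw.set_index("gene_id")
    return GeneAnnotation(raw)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    out = annotation.table.copy()
    out["exon_lengths"] = [
        "" if e is None else ",".join(str(x) for x in e)
        for e in out["exon_lengths"]
    ]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_centroids(path) -> CentroidSet:
    """Read a genes-x-subtypes TSV (first column gene id)."""
    path = Path(path)
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    raw = raw.set_index(gene_col)
    numeric = raw.apply(pd.to_numeric, errors="raise")
    return CentroidSet(numeric)


def write_centroids(centroids: CentroidSet, path) -> None:
    centroids.data.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> PairedDesign:
    """Read a TSV with columns pair_id, sample_a, sample_b and optional
    platform, age_class."""
    path = Path(path)
    raw = _read_tsv(path)
    for col in ("pair_id", "sample_a", "sample_b"):
        if col not in raw.columns:
            raise ValueError(f"{path}: design missing column {col!r}")
    return PairedDesign(raw.set_index("pair_id"))


def write_design(design: PairedDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="pair_id")


# ---------------------------------------------------------------------------
# optional GTF support
# ---------------------------------------------------------------------------

def annotation_from_gtf(
    path, biotype_map: Mapping[str, str] | None = None
) -> GeneAnnotation:
    """Extract a GeneAnnotation from an Ensembl-dialect GTF.

    Transcript class comes from the ``gene_biotype`` attribute through
    ``biotype_map`` (default :data:`DEFAULT_BIOTYPE_MAP`); genes whose
    biotype is absent from the map are skipped with a warning.  Transcript
    length is the union-of-exons length (GTF coordinates are 1-based
    inclusive, so an exon spans ``end - start + 1`` bp); exon lengths are
    recorded in 5'->3' order on the gene strand.
    """
    import gffutils

    biotype_map = dict(biotype_map or DEFAULT_BIOTYPE_MAP)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    skipped = []
    for gene in db.features_of_type("gene"):
        biotype = (gene.attributes.get("gene_biotype") or [None])[0]
        if biotype not in biotype_map:
            skipped.append(gene.id)
            continue
        exons = list(db.children(gene, featuretype="exon"))
        if not exons:
            skipped.append(gene.id)
            continue
        # union of exon intervals over all transcripts of the gene
        intervals = sorted((e.start, e.end) for e in exons)
        merged: list[list[int]] = []
        for start, end in intervals:
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        lengths = [end - start + 1 for start, end in merged]
        if gene.strand == "-":
            lengths = lengths[::-1]
        records.append(
            {
                "gene_id": gene.id,
                "transcript_class": biotype_map[biotype],
                "transcript_length": sum(lengths),
                "exon_lengths": tuple(lengths),
            }
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} GTF genes with unmapped biotype or no "
            f"exons: {skipped[:5]}...",
            stacklevel=2,
        )
    if not records:
        raise ValueError(f"no usable gene records in GTF {path}")
    return GeneAnnotation(pd.DataFrame(records).set_index("gene_id"))


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: name<TAB>description<TAB>gene...

    Returns a mapping from set name to the set of member gene ids.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line needs name, description and "
                    "at least one gene"
                )
            name = parts[0].strip()
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{line_no}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets
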