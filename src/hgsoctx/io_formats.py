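"""Readers and writers for every external format the pipeline touches.

All tabular formats are UTF-8, tab-separated, newline-terminated. Internal
coordinates are 0-based half-open; BED input is taken as-is, SEG-like
segment tables are declared 1-based inclusive and converted on read (and
back on write). Gene and sample identifiers are opaque strings that must be
consistent across inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .genomic_scores import AlleleSegment


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with an optional log2(TPM+1) view.

    Invariants: non-negative values, unique gene and sample identifiers,
    at least 2 genes and 2 samples.
    """

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.tpm.index
        cols = self.tpm.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        if self.tpm.shape[0] < 2 or self.tpm.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=2 genes and >=2 samples, got {self.tpm.shape}"
            )
        values = self.tpm.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative values")
        self.tpm.index = idx.astype(str)
        self.tpm.columns = cols.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return self.tpm.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.tpm.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpm.shape

    def log2(self) -> pd.DataFrame:
        """Derived view log2(TPM + 1)."""
        return np.log2(self.tpm + 1.0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.tpm.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.tpm.loc[:, list(sample_ids)].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.tpm.index]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.tpm.loc[list(gene_ids)].copy())


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, header=0, encoding="utf-8", thousands=None
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed TSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing cells")
    return df


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TPM TSV (header = sample ids, first column = gene ids)."""
    df = _read_tsv_matrix(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.tpm.to_csv(path, sep="\t", index_label="gene_id", encoding="utf-8")


# ---------------------------------------------------------------------------
# Allele-specific segments (SEG-like, 1-based inclusive on disk)

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "cn_total", "cn_minor"]


def read_allele_segments(path: str | Path) -> list[AlleleSegment]:
    """Read a SEG-like TSV (columns sample, chrom, start, end, cn_total, cn_minor).

    On-disk coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention (start-1, end unchanged). Segments
    are returned sorted by (sample, chrom, start); overlapping segments
    within a sample-chromosome are rejected.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing segment columns {missing}")
    segments = []
    for row in df.itertuples(index=False):
        segments.append(
            AlleleSegment(
                sample_id=str(row.sample),
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                cn_total=int(row.cn_total),
                cn_minor=int(row.cn_minor),
            )
        )
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    for a, b in zip(segments, segments[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start < a.end:
            raise ValidationError(
                f"overlapping segments in {a.sample_id}:{a.chrom} at {b.start}"
            )
    return segments


def write_allele_segments(segments: Iterable[AlleleSegment], path: str | Path) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start": s.start + 1,  # back to 1-based inclusive
            "end": s.end,
            "cn_total": s.cn_total,
            "cn_minor": s.cn_minor,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<tab>description<tab>gene1<tab>gene2..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Gene coordinates (BED)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneCoordinates:
    """Per-gene genomic intervals, 0-based half-open, one record per gene."""

    records: dict[str, GeneRecord]

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def chrom_of(self, gene_id: str) -> str:
        return self.records[gene_id].chrom


def read_gene_coordinates(path: str | Path) -> GeneCoordinates:
    """Read gene intervals from BED (chrom, start, end, name[, score, strand])."""
    records: dict[str, GeneRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line needs >=4 fields")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            if name in records:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {name!r}")
            records[name] = GeneRecord(
                gene_id=name, chrom=chrom, start=int(start), end=int(end), strand=strand
            )
    return GeneCoordinates(records=records)


def write_gene_coordinates(coords: GeneCoordinates, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in coords.records.values():
            fh.write(
                "\t".join(
                    [rec.chrom, str(rec.start), str(rec.end), rec.gene_id, "0", rec.strand]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Clinical table

GRADES = ("G1", "G2", "G3")
FIGO_STAGES = ("I", "II", "III", "IV")
RESIDUAL = ("microscopic", "lt1cm", "ge1cm")
VITAL = ("alive", "death", "lfu")

#: label dictionary mapping common source spellings to canonical tokens
CLINICAL_LABEL_MAP: dict[str, dict[str, str]] = {
    "grade": {g: g for g in GRADES} | {"1": "G1", "2": "G2", "3": "G3"},
    "figo_stage": {s: s for s in FIGO_STAGES},
    "neoadjuvant": {
        "yes": "yes", "no": "no", "true": "yes", "false": "no", "1": "yes", "0": "no",
    },
    "residual": {
        "microscopic": "microscopic",
        "<1cm": "lt1cm", "lt1cm": "lt1cm",
        ">=1cm": "ge1cm", "ge1cm": "ge1cm",
    },
    "vital_status": {"alive": "alive", "death": "death", "lfu": "lfu", "dead": "death"},
}

_CLINICAL_COLUMNS = [
    "sample_id", "age", "grade", "figo_stage", "neoadjuvant",
    "residual", "vital_status", "followup_years",
]


@dataclass
class ClinicalTable:
    """Validated per-sample clinical covariates.

    Missing values are encoded as NA (empty string on disk), never dropped.
    ``followup_years`` must be present whenever ``vital_status`` is.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table missing columns {missing}")
        df = self.data
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in clinical table")
        for col, allowed in (
            ("grade", GRADES), ("figo_stage", FIGO_STAGES),
            ("residual", RESIDUAL), ("vital_status", VITAL),
        ):
            bad = df[col].dropna()[~df[col].dropna().isin(allowed)]
            if len(bad):
                raise ValidationError(
                    f"unknown {col} label(s): {sorted(bad.unique().tolist())}"
                )
        bad_neo = df["neoadjuvant"].dropna()[
            ~df["neoadjuvant"].dropna().isin([True, False])
        ]
        if len(bad_neo):
            raise ValidationError(f"unknown neoadjuvant value(s): {bad_neo.tolist()[:5]}")
        has_vital = df["vital_status"].notna()
        if (has_vital & df["followup_years"].isna()).any():
            raise ValidationError("followup_years missing for samples with vital_status")
        fu = df["followup_years"].dropna()
        if (fu < 0).any():
            raise ValidationError("negative followup_years")

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def category_counts(self, column: str) -> dict[str, int]:
        return self.data[column].value_counts(dropna=True).to_dict()


def _map_label(column: str, raw: str, path, lineno) -> str:
    table = CLINICAL_LABEL_MAP[column]
    for key in (raw.strip(), raw.strip().upper(), raw.strip().lower()):
        if key in table:
            return table[key]
    raise ValidationError(f"{path}:{lineno}: unknown {column} label {raw!r}")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the clinical TSV; empty strings become missing values."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical columns {missing}")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        rec: dict[str, object] = {"sample_id": row.sample_id}
        rec["age"] = float(row.age) if row.age != "" else pd.NA
        for col in ("grade", "figo_stage", "residual", "vital_status"):
            raw = getattr(row, col)
            rec[col] = _map_label(col, raw, path, i) if raw != "" else pd.NA
        raw_neo = row.neoadjuvant
        rec["neoadjuvant"] = (
            _map_label("neoadjuvant", raw_neo, path, i) == "yes" if raw_neo != "" else pd.NA
        )
        rec["followup_years"] = (
            float(row.followup_years) if row.followup_years != "" else pd.NA
        )
        rows.append(rec)
    return ClinicalTable(pd.DataFrame(rows, columns=_CLINICAL_COLUMNS))


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.copy()
    df["neoadjuvant"] = df["neoadjuvant"].map(
        lambda v: "" if pd.isna(v) else ("yes" if v else "no")
    )
    df = df.fillna("")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Tissue reference matrix (tissues x genes TPM)


def read_tissue_reference(path: str | Path) -> pd.DataFrame:
    """Read a tissues x genes TPM matrix (first column = tissue name)."""
    df = _read_tsv_matrix(path).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValidationError("tissue reference contains negative TPM")
    return df


def write_tissue_reference(ref: pd.DataFrame, path: str | Path) -> None:
    ref.to_csv(path, sep="\t", index_label="tissue", encoding="utf-8")


# ---------------------------------------------------------------------------
# Plain gene lists (one id per line)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: duplicate gene ids in list")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")
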