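"""Tabular I/O for the proximity-labeling pipeline.

Reads and writes MaxQuant-dialect protein-group tables (``proteinGroups.txt``
style TSV), sample-design tables mapping MS runs to (brain region, construct,
replicate), candidate protein lists, gene-category annotation sets, and result
tables.

All text I/O is UTF-8 with "." as the decimal point. Protein groups are kept
intact (a semicolon-joined accession list stays one row); the group is keyed by
its full joined identifier, and :func:`first_accession` exposes the
first-accession convention used for gene-level joins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MaxQuantDialect",
    "ProteinGroupTable",
    "SampleInfo",
    "SampleDesign",
    "CandidateList",
    "AnnotationSet",
    "read_protein_groups",
    "write_protein_groups",
    "read_sample_design",
    "write_sample_design",
    "read_candidate_list",
    "read_annotation_set",
    "write_results",
    "read_results",
    "normalize_identifier",
    "first_accession",
]

#: full float64 precision: read∘write is the identity and rewriting is byte-stable
FLOAT_FORMAT = "%.17g"

META_COLUMNS = [
    "protein_group_id",
    "gene_symbol",
    "peptide_count",
    "contaminant",
    "reverse",
    "only_by_site",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


@dataclass(frozen=True)
class MaxQuantDialect:
    """Column naming of a MaxQuant ``proteinGroups.txt`` table."""

    id_col: str = "Majority protein IDs"
    gene_col: str = "Gene names"
    peptides_col: str = "Peptides"
    contaminant_col: str = "Potential contaminant"
    reverse_col: str = "Reverse"
    site_col: str = "Only identified by site"
    intensity_prefix: str = "LFQ intensity "

    @property
    def flag_cols(self) -> tuple[str, str, str]:
        return (self.contaminant_col, self.reverse_col, self.site_col)


MAXQUANT = MaxQuantDialect()


@dataclass
class ProteinGroupTable:
    """Validated per-protein-group LFQ table.

    ``frame`` holds one row per protein group with the metadata columns
    ``protein_group_id`` (unique), ``gene_symbol``, ``peptide_count``, the
    three boolean filter flags (``contaminant``, ``reverse``,
    ``only_by_site``), followed by one non-negative float intensity column per
    sample in ``sample_ids``. An intensity of 0 means "not quantified".
    """

    frame: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"protein-group table missing columns: {missing}")
        missing_s = [s for s in self.sample_ids if s not in self.frame.columns]
        if missing_s:
            raise FormatError(f"protein-group table missing sample columns: {missing_s}")
        ids = self.frame["protein_group_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate protein_group_id: {sorted(set(dup))[:5]}")
        intens = self.frame[self.sample_ids].to_numpy(dtype=float)
        if np.isnan(intens).any():
            raise FormatError("intensities contain NaN; unquantified must be 0")
        if (intens < 0).any():
            raise FormatError("negative intensity values")
        if (self.frame["peptide_count"].to_numpy() < 0).any():
            raise FormatError("negative peptide counts")

    def __len__(self) -> int:
        return len(self.frame)

    def intensities(self, samples: Iterable[str] | None = None) -> pd.DataFrame:
        """Intensity block indexed by protein_group_id."""
        cols = list(samples) if samples is not None else self.sample_ids
        return self.frame.set_index("protein_group_id")[cols].astype(float)

    def subset(self, mask) -> "ProteinGroupTable":
        return ProteinGroupTable(self.frame[mask].reset_index(drop=True), list(self.sample_ids))

    def equals(self, other: "ProteinGroupTable") -> bool:
        return self.sample_ids == other.sample_ids and self.frame.equals(other.frame)


@dataclass(frozen=True)
class SampleInfo:
    region: str
    construct: str  # "CD" (binding-competent bait) or "DM" (binding-dead control)
    replicate: int

    def __post_init__(self) -> None:
        if self.construct not in ("CD", "DM"):
            raise FormatError(f"construct must be CD or DM, got {self.construct!r}")
        if self.replicate < 1:
            raise FormatError("replicate numbers start at 1")


@dataclass
class SampleDesign:
    """Maps sample ids to (region, construct, replicate)."""

    samples: dict[str, SampleInfo]

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for info in self.samples.values():
            seen.setdefault(info.region, None)
        return list(seen)

    def samples_for(self, region: str, construct: str) -> list[str]:
        return [
            sid
            for sid, info in self.samples.items()
            if info.region == region and info.construct == construct
        ]

    def check_covers(self, table: ProteinGroupTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.samples]
        if missing:
            raise FormatError(f"sample design missing entries for: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.samples),
                "region": [i.region for i in self.samples.values()],
                "construct": [i.construct for i in self.samples.values()],
                "replicate": [i.replicate for i in self.samples.values()],
            }
        )


@dataclass(frozen=True)
class CandidateList:
    """A deduplicated, namespace-normalized set of protein/gene identifiers."""

    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(not m for m in self.members):
            raise FormatError("candidate list contains empty identifiers")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnnotationSet:
    """A gene-category annotation, e.g. the ribosomal-component gene set."""

    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"annotation set {self.category!r} is empty")


def normalize_identifier(raw: str, casefold: bool = True) -> str:
    """Strip whitespace and (by default) upper-case an identifier."""
    s = str(raw).strip()
    return s.upper() if casefold else s


def first_accession(protein_group_id: str) -> str:
    """First accession of a semicolon-joined protein-group identifier."""
    return protein_group_id.split(";")[0].strip()


def _parse_flag(value, column: str, strict: bool) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    s = str(value).strip()
    if s == "+":
        return True
    if s == "" or s.lower() == "nan":
        return False
    msg = f"unexpected value {s!r} in flag column {column!r} (expected '+' or empty)"
    if strict:
        raise FormatError(msg)
    warnings.warn(msg)
    return False


def read_protein_groups(
    path, dialect: MaxQuantDialect = MAXQUANT, strict_flags: bool = True
) -> ProteinGroupTable:
    """Read a MaxQuant-dialect protein-group TSV.

    Flag cells holding the literal ``"+"`` parse to True, empty cells to
    False; any other content raises :class:`FormatError` when
    ``strict_flags`` or warns and parses to False otherwise. Missing
    intensity cells become 0 (not quantified).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = [dialect.id_col, dialect.gene_col, dialect.peptides_col, *dialect.flag_cols]
    for col in mandatory:
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    sample_cols = [c for c in raw.columns if c.startswith(dialect.intensity_prefix)]
    if not sample_cols:
        raise FormatError(
            f"no intensity columns with prefix {dialect.intensity_prefix!r} in {path}"
        )
    sample_ids = [c[len(dialect.intensity_prefix):] for c in sample_cols]

    frame = pd.DataFrame(
        {
            "protein_group_id": raw[dialect.id_col].str.strip(),
            "gene_symbol": raw[dialect.gene_col].str.strip(),
            "peptide_count": pd.to_numeric(raw[dialect.peptides_col]).astype(int),
            "contaminant": [
                _parse_flag(v, dialect.contaminant_col, strict_flags)
                for v in raw[dialect.contaminant_col]
            ],
            "reverse": [
                _parse_flag(v, dialect.reverse_col, strict_flags)
                for v in raw[dialect.reverse_col]
            ],
            "only_by_site": [
                _parse_flag(v, dialect.site_col, strict_flags)
                for v in raw[dialect.site_col]
            ],
        }
    )
    for sid, col in zip(sample_ids, sample_cols):
        vals = raw[col].replace("", "0")
        # numpy's str->float64 conversion is correctly rounded (pd.to_numeric is not)
        frame[sid] = vals.to_numpy(dtype=float)
    return ProteinGroupTable(frame, sample_ids)


def write_protein_groups(
    table: ProteinGroupTable, path, dialect: MaxQuantDialect = MAXQUANT
) -> None:
    """Write a protein-group table back in the MaxQuant dialect (round-trips)."""
    out = pd.DataFrame()
    out[dialect.id_col] = table.frame["protein_group_id"]
    out[dialect.gene_col] = table.frame["gene_symbol"]
    out[dialect.peptides_col] = table.frame["peptide_count"]
    for col, name in zip(dialect.flag_cols, ("contaminant", "reverse", "only_by_site")):
        out[col] = np.where(table.frame[name], "+", "")
    for sid in table.sample_ids:
        out[dialect.intensity_prefix + sid] = table.frame[sid]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_sample_design(path) -> SampleDesign:
    """Read a sample-design TSV with columns sample_id, region, construct, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "region", "construct", "replicate"):
        if col not in df.columns:
            raise FormatError(f"sample design missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design")
    samples = {
        row.sample_id: SampleInfo(row.region, row.construct, int(row.replicate))
        for row in df.itertuples()
    }
    return SampleDesign(samples)


def write_sample_design(design: SampleDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def _read_delim(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_candidate_list(
    path, column: str | None = None, casefold: bool = True, provenance: str | None = None
) -> CandidateList:
    """Read a candidate list from a one- or multi-column CSV/TSV.

    ``column`` names the identifier column; the first column is used when
    omitted. Identifiers are whitespace-stripped, upper-cased unless
    ``casefold=False``, and deduplicated.
    """
    df = _read_delim(path)
    if df.empty or not len(df.columns):
        raise FormatError(f"candidate list {path} is empty")
    col = column if column is not None else df.columns[0]
    if col not in df.columns:
        raise FormatError(f"candidate list missing identifier column {col!r}")
    ids = {normalize_identifier(v, casefold) for v in df[col] if str(v).strip()}
    if not ids:
        raise FormatError(f"candidate list {path} has no identifiers")
    return CandidateList(frozenset(ids), provenance or str(path))


def read_annotation_set(
    path, category: str, column: str | None = None, casefold: bool = True
) -> AnnotationSet:
    """Read a gene-category annotation (same format as a candidate list)."""
    lst = read_candidate_list(path, column=column, casefold=casefold)
    return AnnotationSet(category, lst.members)


def write_results(records: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a result table as TSV or JSON with a stable column order.

    The column order is the DataFrame's own; floats are rendered with the
    module-level :data:`FLOAT_FORMAT` so rewriting is byte-stable.
    """
    path = Path(path)
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    elif format == "json":
        def _cell(v):
            if isinstance(v, (np.floating, float)):
                if np.isnan(v):
                    return None
                return float(FLOAT_FORMAT % v)
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.bool_,)):
                return bool(v)
            return v

        rows = [
            {col: _cell(v) for col, v in zip(records.columns, row)}
            for row in records.itertuples(index=False, name=None)
        ]
        payload = {"columns": list(records.columns), "records": rows}
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return pd.DataFrame(payload["records"], columns=payload["columns"])
    raise ValueError(f"unknown results format {format!r}")
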