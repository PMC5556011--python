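"""Readers, writers and validated containers for the formats the pipeline touches.

Tables are tab-separated with gene rows and a sample-ID header; sequences are
FASTA; gene sets are GMT. All writers round-trip byte-for-byte with the readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_KINDS = ("counts", "FPKM", "CPM", "log2")

SMALL_RNA_CLASSES = (
    "mRNA",
    "miRNA",
    "snRNA",
    "snoRNA_CD",
    "snoRNA_HACA",
    "snoRNA_orphan",
    "scaRNA",
    "other",
)


class FormatError(ValueError):
    """A malformed external file; the message carries the offending location."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table tagged with the kind of values it holds.

    ``kind`` is one of counts | FPKM | CPM | log2.  Counts must be
    integer-valued and non-negative; FPKM/CPM must be non-negative; log2-scale
    values may be negative.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown expression kind {self.kind!r}")
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if np.isnan(arr).any():
            raise FormatError("missing values in expression matrix")
        if self.kind != "log2" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value for gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if self.kind == "counts" and not np.allclose(arr, np.round(arr)):
            raise FormatError("counts matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.kind)


@dataclass
class SampleMetadata:
    """Per-sample group labels (case | control) plus free-form covariates."""

    table: pd.DataFrame  # index: sample_id; column "group"; rest covariates

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise FormatError("metadata lacks a 'group' column")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r} in metadata")
        bad = set(self.table["group"]) - {"case", "control"}
        if bad:
            raise FormatError(f"unknown group label(s) {sorted(bad)!r}")

    def groups(self) -> tuple[list[str], list[str]]:
        """(case sample IDs, control sample IDs), in metadata order."""
        g = self.table["group"]
        return list(g.index[g == "case"]), list(g.index[g == "control"])

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")


@dataclass
class GeneAnnotation:
    """Gene lengths (nt) and small-RNA class labels."""

    table: pd.DataFrame  # index: gene_id; columns: length_nt, rna_class

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r} in annotation")
        if "length_nt" in self.table.columns:
            if (self.table["length_nt"] < 1).any():
                bad = self.table.index[self.table["length_nt"] < 1][0]
                raise FormatError(f"non-positive length for gene {bad!r}")

    def lengths_for(self, genes: Iterable[str]) -> pd.Series:
        genes = list(genes)
        missing = set(genes) - set(self.table.index)
        if missing:
            raise FormatError(f"genes without length annotation: {sorted(missing)[:5]}")
        return self.table.loc[genes, "length_nt"]


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"duplicate members in gene set {self.set_id!r}")


# ---------------------------------------------------------------------------
# expression / metadata / annotation tables


def read_expression(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a tab-separated genes x samples table; first column is gene IDs."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header:
        raise FormatError(f"{path}:1: expected tab-separated columns")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        return ExpressionMatrix(df, kind)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    df = ann.table.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercased sequence map.

    U/T are preserved as read; the comparison layer normalizes on demand.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            sets.append(GeneSet(cols[0], cols[1], tuple(cols[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# JSON (synthetic truth, reports)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
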