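"""Readers and writers for the on-disk artifacts of the pipeline.

Three text formats are supported:

* expression matrices as TSV (header row of sample ids, first column of
  gene ids) or GCT 1.2;
* gene-set collections as GMT (``name<TAB>description<TAB>gene...``);
* sample annotations as TSV with ``sample_id`` and ``group`` columns.

Gene and sample identifiers are opaque, case-sensitive strings; no alias
resolution is attempted.  Duplicate gene rows collapse to their per-sample
maximum (the long-standing GSEA convention) with a logged warning.  All
numeric output is written with 12 significant digits so that write/read
round-trips reproduce values to better than 1e-9 relative error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TAGS = ("raw", "log2")

#: numeric formatting used by every TSV writer; 12 significant digits keep
#: round-trips within the 1e-9 relative-error contract
FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """File does not conform to the declared dialect."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus a scale tag.

    ``data`` is a genes-by-samples DataFrame whose index holds gene ids and
    whose columns hold sample ids.  ``scale_tag`` records whether values are
    nonnegative raw-scale quantities (``"raw"``) or log2-scale values that
    may be negative (``"log2"``); the pipeline never interprets the unit
    beyond that distinction.
    """

    data: pd.DataFrame
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )
        if self.data.shape[0] == 0:
            raise ValidationError("expression matrix has no genes")
        if self.data.shape[1] == 0:
            raise ValidationError("expression matrix has no samples")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains missing/non-finite values")
        if self.scale_tag == "raw" and (values < 0).any():
            raise ValidationError("raw-scale matrix contains negative values")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        if not present:
            raise ValidationError("no requested genes present in matrix")
        return ExpressionMatrix(self.data.loc[present].copy(), self.scale_tag)

    def equals(self, other: "ExpressionMatrix", rtol: float = 1e-9) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.scale_tag == other.scale_tag
            and np.allclose(self.values, other.values, rtol=rtol, atol=0)
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of unique gene ids."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered list of gene sets with unique names (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class SampleAnnotation:
    """Per-sample group labels plus optional covariates.

    ``table`` is indexed by sample id and carries at least a ``group``
    column; any further columns are treated as covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValidationError("annotation needs a 'group' column")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in annotation")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        self.table["group"] = self.table["group"].astype(str)

    @classmethod
    def from_groups(cls, groups: Mapping[str, str]) -> "SampleAnnotation":
        return cls(pd.DataFrame({"group": pd.Series(dict(groups))}))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def indicator(self, group: str) -> np.ndarray:
        """0/1 vector marking membership of ``group``, in table order."""
        return (self.table["group"] == group).to_numpy(dtype=float)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValidationError(f"annotation samples absent from matrix: {sorted(missing)}")


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by per-sample maximum", n)
        df = df.groupby(level=0, sort=False).max()
    return df


def read_expression(path: str | Path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a TSV or GCT 1.2 expression matrix.

    The dialect is sniffed from the first line: a ``#1.2`` version line
    selects GCT, anything else is treated as plain TSV with gene ids in the
    first column and sample ids in the header row.  Column order in the file
    is the sample order of the returned matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1."):
        return _read_gct(path, scale_tag)
    if "\t" not in first:
        raise FormatError(f"{path}: header row is not tab-separated")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression values: {exc}") from exc
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, scale_tag)


def _read_gct(path: Path, scale_tag: str) -> ExpressionMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: unsupported GCT version line {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer GCT dimensions") from exc
        body = pd.read_csv(fh, sep="\t")
    if body.columns[:2].tolist() != ["NAME", "Description"]:
        raise FormatError(f"{path}: GCT body must start with NAME and Description columns")
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: declared dims ({n_genes} x {n_samples}) do not match body "
            f"({body.shape[0]} x {body.shape[1] - 2})"
        )
    df = body.set_index("NAME").drop(columns=["Description"])
    df.index = df.index.astype(str)
    df = _collapse_duplicate_genes(df.astype(float))
    return ExpressionMatrix(df, scale_tag)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> Path:
    """Write a matrix as TSV (default) or GCT 1.2; returns the path."""
    path = Path(path)
    if dialect == "tsv":
        out = matrix.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    elif dialect == "gct":
        n_genes, n_samples = matrix.shape
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            body = matrix.data.copy()
            body.insert(0, "Description", "na")
            body.index.name = "NAME"
            body.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a TSV with ``sample_id`` and ``group`` columns (extras kept)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: annotation needs sample_id and group columns")
    return SampleAnnotation(df.set_index("sample_id"))


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> Path:
    path = Path(path)
    out = annotation.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    return path
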