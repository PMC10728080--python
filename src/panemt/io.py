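"""Readers, writers and validated containers for the pipeline's file formats.

Canonical on-disk dialect is UTF-8, tab-delimited TSV with a header row.
Expression matrices may also be supplied as GCT 1.2; gene sets as GMT.
Readers validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of continuous (log-scale) expression values.

    ``data`` is indexed by gene id with one column per sample id.  Identifiers
    must be unique and values finite; construction enforces both.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        self.data = self.data.astype(float)

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

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    Required columns: ``sample_id``.  Recognized optional columns:
    ``survival_time`` (months, >= 0), ``event`` (0/1), ``cancer_type``,
    ``estimate_score`` and arbitrary categorical covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValidationError("clinical table requires a sample_id column")
        _check_unique(self.data["sample_id"], "sample ids")
        self.data = self.data.set_index("sample_id", drop=False) if self.data.index.name != "sample_id" else self.data
        if "survival_time" in self.data:
            t = self.data["survival_time"].dropna()
            if (t < 0).any():
                raise ValidationError("negative survival_time")
        if "event" in self.data:
            ev = self.data["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValidationError("event values must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])


VALID_OMICS_KINDS = ("mutation", "cnv", "methylation")


@dataclass
class OmicsMatrix:
    """Gene/probe-by-sample omics matrix.

    ``kind`` selects the value domain: binary for mutation, continuous
    GISTIC-style for cnv, beta in [0, 1] for methylation.  ``probe_to_gene``
    maps methylation probes onto genes.
    """

    kind: str
    data: pd.DataFrame
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_OMICS_KINDS:
            raise ValidationError(f"unknown omics kind {self.kind!r}")
        _check_unique(self.data.index, "gene/probe ids")
        _check_unique(self.data.columns, "sample ids")
        if self.data.isna().any().any():
            raise ValidationError(f"{self.kind} matrix contains missing values")
        vals = self.data.to_numpy()
        if self.kind == "mutation" and not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation matrix must be binary")
        if self.kind == "methylation" and ((vals < 0) | (vals > 1)).any():
            raise ValidationError("methylation beta values must lie in [0, 1]")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # Duplicate gene rows (probe-level input) collapse to the per-sample max.
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by per-sample maximum", n)
        df = df.groupby(level=0, sort=False).max()
    return df


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix from TSV or GCT 1.2.

    ``missing`` is one of ``error`` (reject files with missing values) or
    ``mean`` (impute by per-gene mean).  Duplicate gene rows are collapsed
    by per-sample maximum.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        _check_unique(header, "sample ids")
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"expected GCT header '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError("malformed GCT dimension row")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"GCT dimension row says {(n_genes, n_samples)}, data is {df.shape}"
            )
    else:
        raise FormatError(f"unknown expression format {format!r}")

    _check_unique(df.columns, "sample ids")
    df = _collapse_duplicate_genes(df)
    df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        if missing == "mean":
            df = df.T.fillna(df.mean(axis=1)).T
        else:
            raise ValidationError(
                "expression matrix contains missing values (use missing='mean' to impute)"
            )
    return ExpressionMatrix(df)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            seen: list[str] = []
            for g in genes:
                if g not in seen:
                    seen.append(g)
            sets[name] = seen
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_omics_matrix(
    path: str | Path,
    kind: str,
    probe_map: Mapping[str, str] | None = None,
) -> OmicsMatrix:
    """Read an omics matrix (wide TSV), or a long (sample, gene) mutation table.

    A mutation input whose header is exactly ``sample_id<TAB>gene`` is pivoted
    to a binary gene-by-sample matrix; anything else is read as a wide matrix
    with gene/probe rows and sample columns.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if kind == "mutation" and header[:2] == ["sample_id", "gene"] and len(header) == 2:
        long = pd.read_csv(path, sep="\t")
        df = (
            long.assign(value=1.0)
            .pivot_table(index="gene", columns="sample_id", values="value", fill_value=0.0)
        )
        df.index.name = None
        df.columns.name = None
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(kind=kind, data=df, probe_to_gene=dict(probe_map) if probe_map else None)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# writers


def write_table(obj, path: str | Path) -> None:
    """Write any tabular pipeline object as TSV with a deterministic layout.

    DataFrames are written with their index when it is named (or non-trivial);
    ExpressionMatrix / OmicsMatrix write their gene-by-sample tables;
    ClinicalTable writes its records without the redundant index.
    """
    path = Path(path)
    if isinstance(obj, ExpressionMatrix):
        obj.data.to_csv(path, sep="\t")
    elif isinstance(obj, OmicsMatrix):
        obj.data.to_csv(path, sep="\t")
    elif isinstance(obj, ClinicalTable):
        obj.data.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, pd.DataFrame):
        keep_index = obj.index.name is not None or not obj.index.equals(
            pd.RangeIndex(len(obj))
        )
        obj.to_csv(path, sep="\t", index=keep_index)
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep="\t")
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} as a table")
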