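"""Reading and validation of expression matrices, embeddings, gene lists and
cluster assignments, plus the composition-table writer.

Supported external formats
--------------------------
Expression
    Dense delimited text (CSV, or TSV auto-detected from a ``.tsv``/``.txt``
    extension) with a header row and an id column, or a MatrixMarket triple:
    ``matrix.mtx`` with ``genes.tsv`` and ``barcodes.tsv`` siblings in the
    same directory (the droplet-pipeline export convention).
Coordinates
    Delimited text with header columns ``cell_id,x,y`` — the typical
    UMAP/t-SNE export.
Gene lists
    Plain text, one gene symbol per line; ``#`` begins a comment.
Cluster assignments
    Delimited text with header columns ``cell_id,cluster``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .errors import FormatError, GeneNotFoundError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "GeneGroup",
    "GeneListSpec",
    "ClusterAssignment",
    "read_expression_matrix",
    "read_coordinates",
    "read_gene_lists",
    "read_cluster_assignment",
    "align_cells",
    "filter_cells_by_gene",
    "write_composition_table",
    "COMPOSITION_COLUMNS",
]

COMPOSITION_COLUMNS = ("cell_id", "gene", "group", "fraction", "intensity", "radius")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A cells x genes matrix of non-negative expression values.

    Values are kept in whatever units the input provides (raw or normalized
    counts); all downstream fractions are computed on the values as given.
    """

    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray  # (n_cells, n_genes) float64

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression matrix contains non-finite values")
        if np.any(values < 0):
            raise ValidationError("expression matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_column(self, gene: str) -> np.ndarray:
        """Expression of one gene across all cells."""
        try:
            j = self.gene_ids.index(gene)
        except ValueError:
            raise GeneNotFoundError(f"gene {gene!r} not in matrix") from None
        return self.values[:, j]

    def subset_cells(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        return ExpressionMatrix(
            cell_ids=tuple(self.cell_ids[i] for i in idx),
            gene_ids=self.gene_ids,
            values=self.values[idx, :],
        )

    def subset_genes(self, genes: Sequence[str]) -> np.ndarray:
        """Column submatrix in the given gene order."""
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise GeneNotFoundError(f"genes not in matrix: {missing}")
        return self.values[:, [pos[g] for g in genes]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.values, other.values)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class Embedding:
    """Per-cell 2-D coordinates from a dimensionality reduction (UMAP, t-SNE)."""

    cell_ids: tuple[str, ...]
    coords: np.ndarray  # (n_cells, 2) float64

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError("embedding coordinates must be cells x 2")
        if coords.shape[0] != len(self.cell_ids):
            raise ValidationError("coordinate rows do not match cell ids")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(coords)):
            raise FormatError("embedding contains non-finite coordinates")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, indices: Sequence[int]) -> "Embedding":
        idx = list(indices)
        return Embedding(
            cell_ids=tuple(self.cell_ids[i] for i in idx),
            coords=self.coords[idx, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Embedding):
            return NotImplemented
        return self.cell_ids == other.cell_ids and np.array_equal(
            self.coords, other.coords
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class GeneGroup:
    """One ordered gene list with a color rule.

    ``color_rule`` is either a single color (``#RRGGBB`` hex or a named
    color) or the name of a registered colormap; the colors module decides
    which at assignment time.
    """

    name: str
    genes: tuple[str, ...]
    color_rule: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        if not self.genes:
            raise ValidationError(f"gene group {self.name!r} is empty")
        _check_unique(self.genes, f"gene (group {self.name!r})")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneListSpec:
    """Ordered gene groups; genes are disjoint across groups."""

    groups: tuple[GeneGroup, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [g.name for g in self.groups]
        _check_unique(names, "group")
        seen: dict[str, str] = {}
        for grp in self.groups:
            for gene in grp.genes:
                if gene in seen:
                    raise ValidationError(
                        f"gene {gene!r} appears in groups {seen[gene]!r} and {grp.name!r}"
                    )
                seen[gene] = grp.name

    @property
    def n_total(self) -> int:
        """Total number of genes over all lists (N_total)."""
        return sum(g.n_genes for g in self.groups)

    @property
    def all_genes(self) -> tuple[str, ...]:
        """Concatenated gene order: groups in order, genes in list order."""
        return tuple(gene for grp in self.groups for gene in grp.genes)

    @property
    def gene_to_group(self) -> dict[str, str]:
        return {gene: grp.name for grp in self.groups for gene in grp.genes}

    def group_sizes(self) -> dict[str, int]:
        return {g.name: g.n_genes for g in self.groups}


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-cell cluster labels."""

    cell_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cluster assignment lengths differ")
        _check_unique(self.cell_ids, "cell")


# ---------------------------------------------------------------------------
# Readers


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_as_rows",
    format: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or a MatrixMarket triple.

    Parameters
    ----------
    path
        The delimited file, or the ``.mtx`` file of a MatrixMarket triple.
    orientation
        ``genes_as_rows`` (the common single-cell export convention, default)
        or ``cells_as_rows``. Internally the matrix is always cells x genes.
    format
        ``delimited`` or ``matrixmarket`` (aliases: ``csv``, ``tsv``,
        ``mtx``); inferred from the extension when omitted (``.mtx`` means
        MatrixMarket). The ``csv``/``tsv`` aliases force the delimiter;
        plain ``delimited`` auto-detects it from the extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("genes_as_rows", "cells_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if format is None:
        format = "matrixmarket" if path.suffix.lower() == ".mtx" else "delimited"
    delimiter = _delimiter_for(path)
    if format in ("csv", "tsv"):
        delimiter = "," if format == "csv" else "\t"
        format = "delimited"
    elif format == "mtx":
        format = "matrixmarket"

    if format == "matrixmarket":
        genes_path = path.with_name("genes.tsv")
        barcodes_path = path.with_name("barcodes.tsv")
        for p in (genes_path, barcodes_path):
            if not p.exists():
                raise FormatError(f"MatrixMarket sibling file missing: {p}")
        try:
            raw = mmread(path)
        except Exception as exc:  # scipy raises plain ValueError on bad headers
            raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=np.float64)
        row_ids = _read_id_column(genes_path)
        col_ids = _read_id_column(barcodes_path)
        if mat.shape != (len(row_ids), len(col_ids)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match "
                f"{len(row_ids)} genes x {len(col_ids)} barcodes"
            )
        frame_values, row_labels, col_labels = mat, row_ids, col_ids
    elif format == "delimited":
        try:
            df = pd.read_csv(path, sep=delimiter, index_col=0)
        except Exception as exc:
            raise FormatError(f"cannot parse delimited file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"no data columns in {path}")
        try:
            values = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression values in {path}: {exc}") from exc
        frame_values = values
        row_labels = [str(i) for i in df.index]
        col_labels = [str(c) for c in df.columns]
    else:
        raise ValidationError(f"unknown format {format!r}")

    if orientation == "genes_as_rows":
        gene_ids, cell_ids = row_labels, col_labels
        values = np.asarray(frame_values, dtype=np.float64).T
    else:
        cell_ids, gene_ids = row_labels, col_labels
        values = np.asarray(frame_values, dtype=np.float64)
    return ExpressionMatrix(cell_ids=tuple(cell_ids), gene_ids=tuple(gene_ids), values=values)


def _read_id_column(path: Path) -> list[str]:
    """First column of a headerless TSV; for two-column 10x-style genes.tsv
    (ensembl id TAB symbol) the symbol column is used."""
    ids: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            ids.append(fields[1] if len(fields) >= 2 else fields[0])
    if not ids:
        raise FormatError(f"empty id file: {path}")
    return ids


def read_coordinates(path: str | Path) -> Embedding:
    """Read a 2-D embedding export with header columns ``cell_id,x,y``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter_for(path))
    except Exception as exc:
        raise FormatError(f"cannot parse coordinate file {path}: {exc}") from exc
    missing = [c for c in ("cell_id", "x", "y") if c not in df.columns]
    if missing:
        raise FormatError(f"coordinate file {path} missing columns: {missing}")
    try:
        coords = df[["x", "y"]].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric coordinate in {path}: {exc}") from exc
    if not np.all(np.isfinite(coords)):
        raise FormatError(f"non-finite coordinate in {path}")
    return Embedding(cell_ids=tuple(str(c) for c in df["cell_id"]), coords=coords)


def read_gene_list_file(path: str | Path) -> tuple[str, ...]:
    """One gene symbol per line; ``#`` starts a comment; blank lines skipped."""
    genes: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    if not genes:
        raise ValidationError(f"gene list file {path} contains no genes")
    return tuple(genes)


def read_gene_lists(
    paths: Sequence[str | Path],
    color_rules: Sequence[str],
) -> GeneListSpec:
    """Read one gene list per path and pair it with its color rule by position.

    Group names are the file stems; groups keep argument order and genes keep
    file line order.
    """
    if len(paths) != len(color_rules):
        raise ValidationError(
            f"{len(paths)} gene lists but {len(color_rules)} color rules"
        )
    if not paths:
        raise ValidationError("at least one gene list is required")
    groups = tuple(
        GeneGroup(name=Path(p).stem, genes=read_gene_list_file(p), color_rule=rule)
        for p, rule in zip(paths, color_rules)
    )
    return GeneListSpec(groups=groups)


def read_cluster_assignment(path: str | Path) -> ClusterAssignment:
    """Read a table with header columns ``cell_id,cluster``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse cluster file {path}: {exc}") from exc
    missing = [c for c in ("cell_id", "cluster") if c not in df.columns]
    if missing:
        raise FormatError(f"cluster file {path} missing columns: {missing}")
    return ClusterAssignment(
        cell_ids=tuple(df["cell_id"]), labels=tuple(df["cluster"])
    )


# ---------------------------------------------------------------------------
# In-memory operations


def align_cells(
    matrix: ExpressionMatrix, embedding: Embedding
) -> tuple[ExpressionMatrix, Embedding]:
    """Restrict matrix and embedding to their common cells.

    Both outputs follow the embedding (plot-file) order so rendering and
    overdraw are deterministic. Dropped-cell counts are logged.
    """
    matrix_pos = {c: i for i, c in enumerate(matrix.cell_ids)}
    keep = [(i, matrix_pos[c]) for i, c in enumerate(embedding.cell_ids) if c in matrix_pos]
    if not keep:
        raise ValidationError("matrix and embedding share no cell ids")
    emb_idx = [i for i, _ in keep]
    mat_idx = [j for _, j in keep]
    dropped_emb = embedding.n_cells - len(keep)
    dropped_mat = matrix.n_cells - len(keep)
    if dropped_emb or dropped_mat:
        logger.info(
            "align_cells: dropped %d embedding cells and %d matrix cells "
            "absent from the other input",
            dropped_emb,
            dropped_mat,
        )
    return matrix.subset_cells(mat_idx), embedding.subset(emb_idx)


def filter_cells_by_gene(
    matrix: ExpressionMatrix,
    gene: str,
    threshold: float,
    mode: str = "greater",
) -> ExpressionMatrix:
    """Keep cells whose expression of ``gene`` exceeds ``threshold``.

    ``mode`` is ``greater`` (strict, e.g. "CD68 > 1" style marker gating) or
    ``greater_equal``. The gene set is unchanged.
    """
    if mode not in ("greater", "greater_equal"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    col = matrix.gene_column(gene)
    mask = col > threshold if mode == "greater" else col >= threshold
    idx = np.flatnonzero(mask)
    logger.info(
        "filter_cells_by_gene: %d of %d cells retained (%s %s %g)",
        idx.size,
        matrix.n_cells,
        gene,
        ">" if mode == "greater" else ">=",
        threshold,
    )
    return matrix.subset_cells(idx.tolist())


def write_composition_table(comps: Iterable, path: str | Path) -> None:
    """Write per-(cell, gene) composition rows as CSV.

    Columns are ``cell_id,gene,group,fraction,intensity,radius``; reals are
    printed at 6 decimal places so repeated runs are byte-identical.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(COMPOSITION_COLUMNS)
            for comp in comps:
                for entry in comp.entries:
                    writer.writerow(
                        [
                            comp.cell_id,
                            entry.gene,
                            entry.group,
                            f"{entry.fraction:.6f}",
                            f"{entry.intensity:.6f}",
                            f"{comp.radius:.6f}",
                        ]
                    )
    except OSError as exc:
        raise OSError(f"cannot write composition table to {path}: {exc}") from exc
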