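"""The numeric core: list-size normalization, slice fractions, color
intensities and glyph radii.

Model
-----
Each plotted cell becomes a pie whose slices are the genes of one or more
ordered gene lists. Plotting lists of unequal length raises a bias: if one
list is twice as long as another but every gene is expressed equally, the
longer list's colors would dominate the pie. The normalization

    Xnorm = X * N_total / N_gene_list

(where ``N_total`` is the number of genes over all lists and ``N_gene_list``
the size of the gene's own list) removes that bias: with equal expression
everywhere, each of ``g`` lists receives exactly ``1/g`` of the pie,
regardless of list sizes. Slice fractions are ``Xnorm_i / sum_j Xnorm_j``.

Two further encodings carry expression *magnitude* rather than composition:

* per-slice color intensity: each gene's expression scaled against a
  robust per-gene ceiling (the ``clip_quantile`` quantile of its positive
  values over the plotted cells), clipped to [0, 1];
* glyph radius: square-root scaling of the cell's total normalized
  expression between ``r_min`` and ``r_max``, so pie *area* is proportional
  to total expression.

No log or other transform is applied internally; fractions are computed on
the expression values as given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import GeneNotFoundError, ValidationError
from .io import Embedding, ExpressionMatrix, GeneGroup, GeneListSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SliceEntry",
    "CellComposition",
    "CompositionConfig",
    "normalize_expression",
    "list_size_weights",
    "compute_fractions",
    "compute_intensities",
    "compute_radius",
    "resolve_genes",
    "build_cell_compositions",
]


@dataclass(frozen=True)
class SliceEntry:
    """One pie slice: a gene, its group, its fraction of the pie and its
    color intensity."""

    gene: str
    group: str
    fraction: float
    intensity: float


@dataclass(frozen=True)
class CellComposition:
    """Per-cell slice fractions, intensities and glyph radius.

    ``is_empty`` marks cells with zero total expression over the plotted
    genes; their fractions are all zero and they render as a small neutral
    dot so the embedding silhouette is preserved.
    """

    cell_id: str
    entries: tuple[SliceEntry, ...]
    radius: float
    is_empty: bool

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("glyph radius must be positive")
        total = sum(e.fraction for e in self.entries)
        if self.is_empty:
            if any(e.fraction != 0.0 for e in self.entries):
                raise ValidationError("empty cell must have all-zero fractions")
        elif abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions of cell {self.cell_id!r} sum to {total!r}, not 1"
            )


@dataclass(frozen=True)
class CompositionConfig:
    """Tunables of the numeric core.

    clip_quantile
        Quantile (over plotted cells) used both as the per-gene intensity
        ceiling and as the per-cell total ceiling for radius scaling; one
        robustness knob against outliers. Default 0.99.
    r_min, r_max
        Glyph radius range in embedding units.
    """

    clip_quantile: float = 0.99
    r_min: float = 0.1
    r_max: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_quantile <= 1.0):
            raise ValidationError("clip_quantile must be in (0, 1]")
        if not (0.0 < self.r_min < self.r_max):
            raise ValidationError("need 0 < r_min < r_max")


def normalize_expression(x: float, n_total: int, n_gene_list: int) -> float:
    """List-size normalized expression: ``x * n_total / n_gene_list``.

    Linear in ``x``; the factor is 1 when a single list is plotted.
    """
    if n_gene_list <= 0:
        raise ValidationError("n_gene_list must be a positive integer")
    if n_total < n_gene_list:
        raise ValidationError("n_total must be at least n_gene_list")
    if x < 0:
        raise ValidationError("expression must be non-negative")
    if n_total == n_gene_list:
        return float(x)  # single-list identity, exact
    return x * n_total / n_gene_list


def list_size_weights(spec: GeneListSpec) -> np.ndarray:
    """Per-gene normalization factors N_total / N_gene_list, in
    concatenated gene-list order."""
    n_total = spec.n_total
    return np.array(
        [n_total / grp.n_genes for grp in spec.groups for _ in grp.genes],
        dtype=np.float64,
    )


def _integer_multipliers(spec: GeneListSpec) -> np.ndarray:
    """Per-gene multipliers L / N_gene_list with L = lcm of the list sizes.

    These differ from the N_total / N_gene_list weights only by the constant
    factor L / N_total, which cancels in the fraction ratio — but being
    integers they keep the numerator and denominator exact for
    integer-valued (count) expression, so each fraction is the correctly
    rounded value of the underlying rational.
    """
    lcm = math.lcm(*(g.n_genes for g in spec.groups))
    return np.array(
        [lcm // grp.n_genes for grp in spec.groups for _ in grp.genes],
        dtype=np.float64,
    )


def compute_fractions(
    values: np.ndarray, spec: GeneListSpec
) -> tuple[np.ndarray, bool]:
    """Slice fractions for one cell.

    Parameters
    ----------
    values
        Expression of the spec's genes for this cell, aligned to
        ``spec.all_genes`` order.

    Returns
    -------
    fractions, is_empty
        ``fractions[i] = Xnorm_i / sum_j Xnorm_j`` when the total is
        positive; all zeros with ``is_empty=True`` otherwise.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (spec.n_total,):
        raise ValidationError(
            f"expected {spec.n_total} values, got shape {values.shape}"
        )
    if np.any(values < 0):
        raise ValidationError("expression values must be non-negative")
    xnorm = values * _integer_multipliers(spec)
    total = float(xnorm.sum())
    if total <= 0.0:
        return np.zeros_like(xnorm), True
    return xnorm / total, False


def compute_intensities(
    matrix: ExpressionMatrix, spec: GeneListSpec, clip_quantile: float = 0.99
) -> np.ndarray:
    """Per-(cell, gene) color intensity in [0, 1].

    For each gene the ceiling is the ``clip_quantile`` quantile of that
    gene's *positive* values over the plotted cells; intensity is
    ``min(X / ceiling, 1)``, monotone nondecreasing in X, and exactly 0 at
    X = 0. A gene never expressed gets intensity 0 everywhere (warned).

    Returns a (n_cells, n_spec_genes) array aligned to ``spec.all_genes``.
    """
    if not (0.0 < clip_quantile <= 1.0):
        raise ValidationError("clip_quantile must be in (0, 1]")
    sub = matrix.subset_genes(spec.all_genes)
    out = np.zeros_like(sub)
    for j, gene in enumerate(spec.all_genes):
        col = sub[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            logger.warning("gene %r has no positive values; intensity set to 0", gene)
            continue
        ceiling = float(np.quantile(positive, clip_quantile))
        if ceiling <= 0:  # numerically impossible, defensive
            continue
        out[:, j] = np.minimum(col / ceiling, 1.0)
    return out


def compute_radius(
    total_norm_expression: float,
    total_max: float,
    r_min: float,
    r_max: float,
) -> float:
    """Glyph radius from total normalized expression.

    ``r_min + (r_max - r_min) * sqrt(min(total/total_max, 1))`` — the square
    root makes glyph *area* proportional to total expression.
    """
    if total_max <= 0:
        raise ValidationError("total_max must be positive")
    if not (0 < r_min < r_max):
        raise ValidationError("need 0 < r_min < r_max")
    if total_norm_expression < 0:
        raise ValidationError("total expression must be non-negative")
    frac = min(total_norm_expression / total_max, 1.0)
    return r_min + (r_max - r_min) * math.sqrt(frac)


def resolve_genes(
    matrix: ExpressionMatrix,
    spec: GeneListSpec,
    policy: str = "drop_warn",
    case_insensitive: bool = False,
) -> GeneListSpec:
    """Reconcile the gene lists with the matrix's gene ids.

    Matching is case-sensitive exact match by default; with
    ``case_insensitive`` both sides are uppercased and the *matrix* spelling
    is kept in the resolved spec. Genes absent from the matrix are dropped
    with a warning naming them (``drop_warn``) or raise (``error``). The
    resolved lists define the N_total and N_gene_list used downstream. A
    group losing all its genes is an error under either policy.
    """
    if policy not in ("drop_warn", "error"):
        raise ValidationError(f"unknown missing-gene policy {policy!r}")
    if case_insensitive:
        lookup: dict[str, str] = {}
        for g in matrix.gene_ids:
            lookup.setdefault(g.upper(), g)
        key = str.upper
    else:
        lookup = {g: g for g in matrix.gene_ids}
        key = lambda s: s  # noqa: E731

    groups: list[GeneGroup] = []
    for grp in spec.groups:
        kept, missing = [], []
        for gene in grp.genes:
            hit = lookup.get(key(gene))
            (kept if hit is not None else missing).append(hit if hit is not None else gene)
        if missing and policy == "error":
            raise GeneNotFoundError(
                f"group {grp.name!r}: genes not in matrix: {missing}"
            )
        if missing:
            logger.warning(
                "group %r: dropping genes absent from matrix: %s",
                grp.name,
                ", ".join(missing),
            )
        if not kept:
            raise ValidationError(
                f"group {grp.name!r} has no genes left after resolution"
            )
        groups.append(GeneGroup(name=grp.name, genes=tuple(kept), color_rule=grp.color_rule))
    return GeneListSpec(groups=tuple(groups))


def build_cell_compositions(
    matrix: ExpressionMatrix,
    embedding: Embedding,
    spec: GeneListSpec,
    config: CompositionConfig | None = None,
) -> list[CellComposition]:
    """One :class:`CellComposition` per embedded cell, in embedding order.

    Inputs must already be aligned (same cells, same order; see
    :func:`pieglyph.io.align_cells`) and the spec resolved against the
    matrix. Deterministic: repeated calls yield identical output.
    """
    config = config or CompositionConfig()
    if matrix.cell_ids != embedding.cell_ids:
        raise ValidationError(
            "matrix and embedding cells differ or are ordered differently; "
            "run align_cells first"
        )
    if not spec.groups:
        raise ValidationError("gene list spec is empty")
    sub = matrix.subset_genes(spec.all_genes)
    weights = list_size_weights(spec)
    xnorm = sub * weights
    totals = xnorm.sum(axis=1)
    positive_totals = totals[totals > 0]
    if positive_totals.size:
        total_max = float(np.quantile(positive_totals, config.clip_quantile))
    else:
        total_max = 1.0  # every cell is empty; radius path is unused
    intensities = compute_intensities(matrix, spec, config.clip_quantile)
    groups_per_gene = [grp.name for grp in spec.groups for _ in grp.genes]
    genes = spec.all_genes

    comps: list[CellComposition] = []
    for i, cell_id in enumerate(embedding.cell_ids):
        fractions, is_empty = compute_fractions(sub[i], spec)
        if is_empty:
            radius = config.r_min / 2.0
        else:
            radius = compute_radius(
                float(totals[i]), total_max, config.r_min, config.r_max
            )
        entries = tuple(
            SliceEntry(
                gene=genes[j],
                group=groups_per_gene[j],
                fraction=float(fractions[j]),
                intensity=float(intensities[i, j]),
            )
            for j in range(len(genes))
        )
        comps.append(
            CellComposition(
                cell_id=cell_id, entries=entries, radius=radius, is_empty=is_empty
            )
        )
    return comps
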