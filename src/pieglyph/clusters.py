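"""Cluster-aggregated "big pies" mode.

One pie per cell cluster: slice fractions come from the cluster's arithmetic
mean expression (fractions are scale-invariant, so the mean and the member
sum give identical compositions), the pie sits at the coordinate centroid,
and its size encodes the member cell count with square-root scaling so pie
*area* is proportional to cell count when ``r_min = 0``.

Per-cluster slice intensities are computed from the mean expression against
the same per-gene clip ceilings as cell mode, so cell-level and
cluster-level figures are color-comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .composition import (
    CellComposition,
    SliceEntry,
    compute_fractions,
)
from .errors import ValidationError
from .io import ClusterAssignment, Embedding, ExpressionMatrix, GeneListSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSummary",
    "summarize_clusters",
    "cluster_radii",
    "cluster_compositions",
]


@dataclass(frozen=True)
class ClusterSummary:
    """Aggregate of one cell cluster.

    ``mean_expression`` is aligned to the spec's concatenated gene order;
    ``entries`` are the composition slices computed from it.
    """

    label: str
    n_cells: int
    centroid: tuple[float, float]
    mean_expression: np.ndarray
    entries: tuple[SliceEntry, ...]
    is_empty: bool

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("cluster must have at least one member")


def summarize_clusters(
    matrix: ExpressionMatrix,
    embedding: Embedding,
    assignment: ClusterAssignment,
    spec: GeneListSpec,
    clip_quantile: float = 0.99,
) -> list[ClusterSummary]:
    """Aggregate expression and position per cluster.

    Every assigned cell must exist in both the matrix and the embedding
    (align inputs first). Summaries are ordered by descending cell count,
    ties broken by label.
    """
    mat_pos = {c: i for i, c in enumerate(matrix.cell_ids)}
    emb_pos = {c: i for i, c in enumerate(embedding.cell_ids)}
    unknown = [
        c for c in assignment.cell_ids if c not in mat_pos or c not in emb_pos
    ]
    if unknown:
        raise ValidationError(
            f"assigned cells absent from matrix or embedding: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )

    members: dict[str, list[str]] = {}
    for cell, label in zip(assignment.cell_ids, assignment.labels):
        members.setdefault(label, []).append(cell)

    sub = matrix.subset_genes(spec.all_genes)
    # per-gene intensity ceilings from CELL-level values, shared with cell mode
    ceilings = np.zeros(spec.n_total)
    for j in range(spec.n_total):
        positive = sub[:, j][sub[:, j] > 0]
        if positive.size:
            ceilings[j] = float(np.quantile(positive, clip_quantile))

    groups_per_gene = [grp.name for grp in spec.groups for _ in grp.genes]
    genes = spec.all_genes

    summaries: list[ClusterSummary] = []
    for label, cells in members.items():
        if not cells:  # defensive; empty clusters cannot normally arise
            logger.warning("cluster %r has no members after alignment; dropped", label)
            continue
        m_idx = [mat_pos[c] for c in cells]
        e_idx = [emb_pos[c] for c in cells]
        mean_expr = sub[m_idx, :].mean(axis=0)
        centroid = embedding.coords[e_idx, :].mean(axis=0)
        fractions, is_empty = compute_fractions(mean_expr, spec)
        intensities = np.where(
            ceilings > 0, np.minimum(np.divide(mean_expr, np.where(ceilings > 0, ceilings, 1.0)), 1.0), 0.0
        )
        entries = tuple(
            SliceEntry(
                gene=genes[j],
                group=groups_per_gene[j],
                fraction=float(fractions[j]),
                intensity=float(intensities[j]),
            )
            for j in range(len(genes))
        )
        summaries.append(
            ClusterSummary(
                label=label,
                n_cells=len(cells),
                centroid=(float(centroid[0]), float(centroid[1])),
                mean_expression=mean_expr,
                entries=entries,
                is_empty=is_empty,
            )
        )
    summaries.sort(key=lambda s: (-s.n_cells, s.label))
    return summaries


def cluster_radii(
    summaries: list[ClusterSummary], r_min: float, r_max: float
) -> list[float]:
    """Pie radius per cluster from its cell count.

    ``r_min + (r_max - r_min) * sqrt(n_k / n_max)``: with ``r_min = 0`` the
    pie-area ratio between any two clusters equals their cell-count ratio.
    """
    if not summaries:
        raise ValidationError("no cluster summaries")
    if r_min < 0 or r_max <= r_min:
        raise ValidationError("need 0 <= r_min < r_max")
    n_max = max(s.n_cells for s in summaries)
    return [
        r_min + (r_max - r_min) * math.sqrt(s.n_cells / n_max) for s in summaries
    ]


def cluster_compositions(
    summaries: list[ClusterSummary], r_min: float, r_max: float
) -> list[CellComposition]:
    """Big-pie compositions: one per cluster, radius from the cell count.

    Empty clusters (all-zero mean expression) get the small-dot radius like
    empty cells.
    """
    radii = cluster_radii(summaries, r_min, r_max)
    comps = []
    for summary, radius in zip(summaries, radii):
        if summary.is_empty:
            radius = max(r_min, 1e-12) / 2.0 if r_min > 0 else r_max / 20.0
        comps.append(
            CellComposition(
                cell_id=summary.label,
                entries=summary.entries,
                radius=max(radius, 1e-12),
                is_empty=summary.is_empty,
            )
        )
    return comps
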