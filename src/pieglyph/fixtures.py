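"""Synthetic single-cell data generator.

Emulates the shape of a clustered scRNA-seq export at desk scale: K Gaussian
blobs in a 2-D embedding (cluster centers evenly spaced on a circle), and a
non-negative count matrix in which each cluster has its own "program" of
marker genes expressed at a high mean inside the cluster and at a low
background mean elsewhere. Counts are negative-binomial to emulate the
overdispersion of droplet scRNA-seq; the distributional choice is test
scaffolding, not a biological claim.

Everything is driven by a single integer seed: the same seed reproduces the
same matrix, coordinates and labels elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import (
    ClusterAssignment,
    Embedding,
    ExpressionMatrix,
    GeneGroup,
    GeneListSpec,
)

__all__ = ["FixtureSpec", "generate_fixture", "write_fixture_files"]

# colormaps cycled over program groups; perceptually distinct pairs
_GROUP_COLORMAPS = ("winter", "autumn", "summer", "cool", "copper", "spring")

_CENTER_RING_RADIUS = 10.0  # embedding units; fixed so blobs separate at default spread


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic dataset.

    Defaults give three well-separated clusters of 100 cells, five program
    genes each, with a 100x program-to-background mean ratio — strong,
    clean marker structure on which the full pipeline should recover every
    cell's home program.
    """

    n_clusters: int = 3
    cells_per_cluster: tuple[int, ...] = (100, 100, 100)
    n_program_genes: int = 5
    program_mean: float = 10.0
    background_mean: float = 0.1
    dispersion: float = 2.0
    cluster_spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells_per_cluster", tuple(self.cells_per_cluster))
        if self.n_clusters < 1:
            raise ValidationError("need at least one cluster")
        if len(self.cells_per_cluster) != self.n_clusters:
            raise ValidationError("cells_per_cluster length must equal n_clusters")
        if any(n < 1 for n in self.cells_per_cluster):
            raise ValidationError("every cluster needs at least one cell")
        if self.n_program_genes < 1:
            raise ValidationError("need at least one program gene per cluster")
        if not (self.program_mean > 0 and np.isfinite(self.program_mean)):
            raise ValidationError("program_mean must be positive and finite")
        if self.background_mean < 0 or not np.isfinite(self.background_mean):
            raise ValidationError("background_mean must be non-negative and finite")
        if self.dispersion <= 0 or self.cluster_spread <= 0:
            raise ValidationError("dispersion and cluster_spread must be positive")


def _nb_sample(
    rng: np.random.Generator, mean: float, dispersion: float, size: tuple[int, ...]
) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion r
    (variance = mean + mean^2 / r). mean = 0 yields exact zeros."""
    if mean <= 0:
        return np.zeros(size, dtype=np.float64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.float64)


def generate_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[ExpressionMatrix, Embedding, ClusterAssignment, GeneListSpec]:
    """Generate matrix, embedding, cluster labels and gene lists.

    Gene ids are ``PG<k>_<j>`` (program gene j of cluster k); the gene-list
    spec has one group per cluster program, each on its own colormap. Cells
    are ordered cluster by cluster; ids are ``cell0000`` onward.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)

    n_cells = sum(spec.cells_per_cluster)
    n_genes = spec.n_clusters * spec.n_program_genes
    cell_ids = tuple(f"cell{i:04d}" for i in range(n_cells))
    gene_ids = tuple(
        f"PG{k}_{j}"
        for k in range(spec.n_clusters)
        for j in range(spec.n_program_genes)
    )
    labels: list[str] = []
    for k, n_k in enumerate(spec.cells_per_cluster):
        labels.extend([f"cluster{k}"] * n_k)

    # counts: program genes hot inside their home cluster, background elsewhere
    values = np.zeros((n_cells, n_genes))
    row = 0
    for k, n_k in enumerate(spec.cells_per_cluster):
        block = _nb_sample(
            rng, spec.background_mean, spec.dispersion, (n_k, n_genes)
        )
        lo = k * spec.n_program_genes
        block[:, lo : lo + spec.n_program_genes] = _nb_sample(
            rng, spec.program_mean, spec.dispersion, (n_k, spec.n_program_genes)
        )
        values[row : row + n_k, :] = block
        row += n_k

    # embedding: isotropic Gaussian blobs around evenly spaced ring centers
    angles = 2.0 * np.pi * np.arange(spec.n_clusters) / spec.n_clusters
    centers = _CENTER_RING_RADIUS * np.column_stack([np.cos(angles), np.sin(angles)])
    if spec.n_clusters == 1:
        centers = np.zeros((1, 2))
    coords = np.zeros((n_cells, 2))
    row = 0
    for k, n_k in enumerate(spec.cells_per_cluster):
        coords[row : row + n_k, :] = centers[k] + rng.normal(
            scale=spec.cluster_spread, size=(n_k, 2)
        )
        row += n_k

    groups = tuple(
        GeneGroup(
            name=f"program{k}",
            genes=tuple(
                f"PG{k}_{j}" for j in range(spec.n_program_genes)
            ),
            color_rule=_GROUP_COLORMAPS[k % len(_GROUP_COLORMAPS)],
        )
        for k in range(spec.n_clusters)
    )

    return (
        ExpressionMatrix(cell_ids=cell_ids, gene_ids=gene_ids, values=values),
        Embedding(cell_ids=cell_ids, coords=coords),
        ClusterAssignment(cell_ids=cell_ids, labels=tuple(labels)),
        GeneListSpec(groups=groups),
    )


def write_fixture_files(
    out_dir: str | Path, spec: FixtureSpec | None = None
) -> dict[str, object]:
    """Generate a fixture and write it in the package's input formats.

    Writes ``expression.csv`` (genes as rows), ``coords.csv``,
    ``clusters.csv`` and one ``<group>.txt`` gene list per program group.
    Returns the file paths plus the groups' color rules, ready to feed the
    CLI.
    """
    import pandas as pd

    spec = spec or FixtureSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, embedding, assignment, gene_spec = generate_fixture(spec)

    expr_path = out_dir / "expression.csv"
    pd.DataFrame(
        matrix.values.T, index=list(matrix.gene_ids), columns=list(matrix.cell_ids)
    ).to_csv(expr_path, float_format="%.6g")

    coords_path = out_dir / "coords.csv"
    pd.DataFrame(
        {
            "cell_id": list(embedding.cell_ids),
            "x": embedding.coords[:, 0],
            "y": embedding.coords[:, 1],
        }
    ).to_csv(coords_path, index=False, float_format="%.6f")

    clusters_path = out_dir / "clusters.csv"
    pd.DataFrame(
        {"cell_id": list(assignment.cell_ids), "cluster": list(assignment.labels)}
    ).to_csv(clusters_path, index=False)

    list_paths, color_rules = [], []
    for grp in gene_spec.groups:
        p = out_dir / f"{grp.name}.txt"
        p.write_text("\n".join(grp.genes) + "\n", encoding="utf-8")
        list_paths.append(p)
        color_rules.append(grp.color_rule)

    return {
        "expression": expr_path,
        "coords": coords_path,
        "clusters": clusters_path,
        "gene_lists": list_paths,
        "color_rules": color_rules,
    }
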