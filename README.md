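# pieglyph

Render every cell of a single-cell RNA-seq embedding (UMAP, t-SNE, or any
2-D coordinate export) as a **pie chart** whose slices show the cell's
expression composition over one or more marker gene lists — instead of the
usual one-gene-per-plot colored dots. One figure then answers questions
that would otherwise take a dozen panels: which marker programs a cell
expresses, in what proportion, and how strongly.

It is written for computational biologists who already have a processed
expression matrix and embedding coordinates (e.g. exported from a Seurat or
scanpy workflow) and want multi-gene, publication-ready overview figures.

## The model

For gene *i* with expression *X* in a cell, the normalized expression is

```
Xnorm = X · N_total / N_gene_list
```

with `N_total` the number of genes over all lists and `N_gene_list` the
size of the gene's own list; the slice fraction is `Xnorm_i / Σ_j Xnorm_j`.
This weighs gene lists of unequal length equally: with `g` lists and equal
expression everywhere, each list gets exactly `1/g` of every pie. On top of
the composition, two magnitude encodings are applied: each slice's color is
interpolated toward white as expression drops (per-gene quantile-clipped
scaling), and the pie radius grows with the cell's total normalized
expression (square-root scaling, so pie *area* is proportional to total).
A cluster mode draws one big pie per cell cluster from its mean expression,
placed at the cluster centroid and sized by cell count. See
`docs/methods.md` for the full account.

## Worked example

Generate a small synthetic dataset (3 clusters × 100 cells, one marker
program per cluster) and plot it:

```
pieglyph make-fixture --out-dir demo --seed 1
pieglyph plot-cells \
    --expression demo/expression.csv --coords demo/coords.csv \
    --gene-list demo/program0.txt --gene-list demo/program1.txt \
    --gene-list demo/program2.txt \
    --color winter --color autumn --color summer \
    --out demo/cells.svg --composition-out demo/composition.csv
```

which prints

```
wrote fixture to demo: expression.csv, coords.csv, clusters.csv, program0.txt, program1.txt, program2.txt
wrote demo/cells.svg and demo/composition.csv
```

`demo/cells.svg` is the pie-glyph embedding with an auto-generated legend
(each program's genes sampled along its colormap). The composition table
starts:

```
cell_id,gene,group,fraction,intensity,radius
cell0000,PG0_0,program0,0.242424,0.268637,0.230675
cell0000,PG0_1,program0,0.303030,0.318471,0.230675
cell0000,PG0_2,program0,0.090909,0.117096,0.230675
cell0000,PG0_3,program0,0.151515,0.141084,0.230675
```

Reading: in cell `cell0000`, gene `PG0_0` occupies 24.24% of the pie, is
drawn at 26.9% color intensity (its expression relative to the gene's
clipped ceiling across cells), and the whole glyph has radius 0.2307 in
embedding units. Per cell, fractions over all 15 genes sum to 1. Cluster
mode works the same way with `plot-clusters --clusters demo/clusters.csv`.

The same pipeline is available as a library:

```python
from pieglyph import (read_expression_matrix, read_coordinates,
                      read_gene_lists, align_cells, resolve_genes,
                      build_cell_compositions)
```

Real data drops in directly: expression as CSV/TSV (genes as rows by
default) or a MatrixMarket `matrix.mtx` + `genes.tsv` + `barcodes.tsv`
triple, coordinates as a `cell_id,x,y` table, gene lists as one-symbol-per-
line text files.

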