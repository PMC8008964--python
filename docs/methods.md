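# Methods

## The visualization model

`pieglyph` renders a 2-D single-cell embedding (UMAP, t-SNE, or any other
per-cell coordinate export) in which each cell is a pie chart instead of a
single-colored dot. The user supplies one or more ordered gene lists, each
with a color rule; every gene becomes one potential slice of every cell's
pie.

**Slice fractions.** For gene *i* with expression *X* in a given cell, the
normalized expression is

    Xnorm = X · N_total / N_gene_list

where `N_total` is the number of genes over all lists and `N_gene_list` the
size of the gene's own list. The slice fraction is `Xnorm_i / Σ_j Xnorm_j`.
The rescaling removes the bias that longer lists would otherwise dominate
the pie: if `g` lists are plotted and every gene carries the same value,
each list receives exactly `1/g` of the pie regardless of list sizes.
`N_total` and `N_gene_list` always refer to the lists *after* reconciliation
with the matrix (missing genes dropped or raised, by policy).

**Intensity.** Composition alone hides magnitude, so each slice's color is
interpolated toward white by `1 − intensity`, where `intensity =
min(X / q_gene, 1)` and `q_gene` is the `clip_quantile` quantile of the
gene's positive values over the plotted cells. Per-gene scaling keeps
weakly expressed markers visible next to highly expressed ones; the
quantile clip (default 0.99) stops single outlier cells from washing out
everything else. Intensity is exactly 0 at zero expression and monotone
nondecreasing in expression. A gene with no positive values anywhere gets
intensity 0 (with a warning). Lightening can be disabled (`-lc` off), in
which case slices show the base colors at full saturation.

**Glyph size.** The cell's total normalized expression maps to a radius

    r = r_min + (r_max − r_min) · sqrt(min(total / total_max, 1))

The square root makes pie *area* — the quantity the eye integrates —
proportional to total expression. `total_max` is the `clip_quantile`
quantile of per-cell totals, sharing the one robustness knob with the
intensity ceiling. Defaults: `r_max` = 1.5% of the larger embedding extent,
`r_min` = `r_max` / 4.

**Zero-expression cells.** A cell expressing none of the listed genes is
flagged `is_empty` and drawn as a neutral gray dot of radius `r_min / 2`
rather than dropped, so cluster silhouettes in the embedding are preserved.

**Expression units.** The tool accepts any non-negative matrix (raw or
library-normalized counts, linear or otherwise) and computes fractions on
the values as given; no log or other transform is applied internally.
Fractions are scale-invariant, so a global rescaling of the matrix changes
nothing; intensities are likewise invariant when `clip_quantile = 1`.

## Color assignment

A group's color rule is either a single color or a colormap name. Colormap
groups sample the *full* map range at positions `i / (n − 1)` for the `i`-th
of `n` genes (a single gene takes position 0); the full span maximizes
distinguishability for long ordered marker lists, e.g. differentiation
markers sorted from early to late. Lightening interpolates in plain RGB
toward white (`b·i + (1 − i)` per channel), which is monotone per channel,
endpoint-exact in floating point, and bit-reproducible. Disambiguation:
strings starting with `#` are hex colors, exact registry names are
colormaps, anything else is tried as a named color — so a color whose name
collides with a colormap (`gray`) must be given as hex.

## Geometry and rendering

Wedges start at 12 o'clock and proceed clockwise in concatenated gene-list
order; zero-fraction genes produce no wedge, and non-empty glyphs tile
360° within 1e-6. Embedding y increases upward; the flip to screen
coordinates happens at raster time. Glyphs are drawn in embedding-file
order with no collision avoidance, so overdraw is deterministic. The legend
occupies a reserved right margin (20% of canvas width), listing genes under
group headers, wrapping into columns of at most 40 rows.

SVG is the reference format: it is emitted directly by this package with
fixed 3-decimal coordinate formatting and no timestamps or generated ids,
so identical inputs yield byte-identical files — a deliberate design choice
that makes figure output testable by byte comparison. Full-circle slices
and empty-cell dots are emitted as `<circle>` elements, partial slices as
`<path>` wedges. PNG output is rasterized through matplotlib's Agg backend
(default 150 dpi).

## Cluster mode ("big pies")

One pie per cluster: per-gene **arithmetic mean** expression over member
cells feeds the same fraction computation (mean was chosen over median so
that the mean-vector composition equals the summed-vector composition
exactly — fractions are scale-invariant and mean and sum differ by `1/n`).
The pie sits at the coordinate centroid; overlaps are not resolved. Radius
follows `r_min + (r_max − r_min)·sqrt(n_k / n_max)`, so with `r_min = 0`
(the CLI default in cluster mode) pie areas are exactly proportional to
cell counts. Per-cluster slice intensities are computed against the same
per-gene cell-level clip ceilings as cell mode, keeping cell and cluster
figures color-comparable. Summaries are ordered by descending cell count
(ties by label).

## Numerical choices

Slice fractions are computed with integer per-list multipliers
`L / N_gene_list`, where `L` is the least common multiple of the list
sizes. The ratio is mathematically identical to using
`N_total / N_gene_list` weights (the constant factor cancels), but because
the multipliers are integers the numerator and denominator remain exact for
integer-valued count data (below 2^53), so every fraction is the correctly
rounded value of the underlying rational — verified in the tests against a
`fractions.Fraction` brute-force oracle, bit-for-bit. The single-list
normalization factor is short-circuited to exactly 1. Degenerate cases: a
group reduced to zero genes by resolution is always an error; an all-empty
matrix sets the (unused) radius cap to 1; quantiles of positive values use
`numpy.quantile` with linear interpolation.

## Synthetic data generator

`pieglyph.fixtures` emulates a clustered scRNA-seq export at desk scale:
K isotropic Gaussian blobs (centers evenly spaced on a ring of radius 10
embedding units, spread 1.0), and per-cluster gene programs drawn
negative-binomially — mean 10 inside the home cluster, 0.1 elsewhere
(a 100× marker contrast), dispersion 2 to mimic droplet overdispersion.
Defaults are 3 clusters × 100 cells × 5 program genes; everything is a
deterministic function of one seed. What it does **not** emulate: library-
size variation between cells, dropout that correlates with expression,
gene–gene correlation within programs, ambient RNA, or realistic cluster
geometry. Tests passing on these fixtures therefore demonstrate the
*numerics and determinism* of the pipeline — conservation, normalization,
recovery of a dominant marker — not robustness to real-data artifacts.

## Known limitations

- Dense in-memory matrices only; very large matrices (≫10⁵ cells) should be
  pre-filtered to the genes of interest.
- No HDF5/loom/AnnData readers; use the delimited or MatrixMarket exports.
- Pie glyphs overlap in dense embeddings; choose `--r-max` accordingly.
- Legend rendering truncates entries that exceed the canvas height.
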