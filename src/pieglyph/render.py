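"""Pie-glyph geometry and figure output (SVG, PNG).

Conventions
-----------
* Wedge angles are degrees measured from 12 o'clock, proceeding clockwise —
  the everyday pie-chart convention. Wedges follow concatenated gene-list
  order; zero-fraction genes produce no wedge.
* Embedding y increases upward (mathematical convention); the flip to
  screen-y happens at raster time.
* Glyphs are drawn in input order, so overdraw is deterministic; there is
  no collision avoidance.
* SVG is the reference output: it is generated directly by this module with
  fixed number formatting and no timestamps, so identical inputs produce
  byte-identical documents. PNG is rasterized through matplotlib.

The legend occupies a reserved right margin (20% of canvas width by
default); genes are listed under group headers and long lists wrap into
columns of at most 40 rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .colors import RGB, ColorAssignment, LegendEntry, apply_intensity
from .composition import CellComposition
from .errors import ValidationError
from .io import Embedding

__all__ = [
    "WedgeSpec",
    "PieGlyph",
    "RenderConfig",
    "default_radius_range",
    "layout_glyph",
    "render_figure",
]

FULL_CIRCLE_EPS = 1e-6


@dataclass(frozen=True)
class WedgeSpec:
    """One pie slice: start/end angles in clockwise degrees from 12 o'clock."""

    start_angle: float
    end_angle: float
    fill: RGB

    @property
    def arc(self) -> float:
        return self.end_angle - self.start_angle


@dataclass(frozen=True)
class PieGlyph:
    """A pie chart at one embedding position.

    ``dot_color`` is set (and ``wedges`` empty) for zero-expression cells,
    which render as a plain dot.
    """

    center: tuple[float, float]
    radius: float
    wedges: tuple[WedgeSpec, ...]
    dot_color: RGB | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("glyph radius must be positive")


@dataclass(frozen=True)
class RenderConfig:
    """Canvas and styling parameters.

    Sizes are pixels; ``dpi`` applies to PNG output only. The legend margin
    is ``legend_fraction`` of the canvas width.
    """

    width: int = 900
    height: int = 700
    lighten_enabled: bool = True
    empty_color: RGB = (0.7, 0.7, 0.7)
    out_format: str = "svg"
    dpi: int = 150
    background: RGB = (1.0, 1.0, 1.0)
    legend_fraction: float = 0.2
    max_legend_rows: int = 40

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.dpi <= 0:
            raise ValidationError("canvas size and dpi must be positive")
        if self.out_format not in ("svg", "png"):
            raise ValidationError(f"unknown output format {self.out_format!r}")
        if not (0.0 <= self.legend_fraction < 0.9):
            raise ValidationError("legend_fraction must be in [0, 0.9)")


def default_radius_range(embedding: Embedding) -> tuple[float, float]:
    """Default glyph radius range from the embedding extent.

    ``r_max`` is 1.5% of the larger coordinate extent (dense plots stay
    readable); ``r_min`` is a quarter of that.
    """
    spans = embedding.coords.max(axis=0) - embedding.coords.min(axis=0)
    extent = float(max(spans.max(), 0.0))
    if extent <= 0:
        extent = 1.0  # degenerate single-point embedding
    r_max = 0.015 * extent
    return r_max / 4.0, r_max


def layout_glyph(
    comp: CellComposition,
    coords: tuple[float, float],
    colors: ColorAssignment,
    config: RenderConfig,
) -> PieGlyph:
    """Turn one cell's composition into pie geometry.

    Wedges start at 12 o'clock and proceed clockwise in gene-list order;
    slice fills are the genes' base colors, lightened toward white by
    (1 - intensity) when lightening is enabled. Empty cells become a neutral
    dot (their radius was already set to half the minimum by the
    composition stage).
    """
    x, y = float(coords[0]), float(coords[1])
    if comp.is_empty:
        return PieGlyph(
            center=(x, y), radius=comp.radius, wedges=(), dot_color=config.empty_color
        )
    wedges: list[WedgeSpec] = []
    cursor = 0.0
    for entry in comp.entries:
        if entry.fraction <= 0.0:
            continue
        arc = 360.0 * entry.fraction
        fill = apply_intensity(
            colors.base[entry.gene], entry.intensity, config.lighten_enabled
        )
        wedges.append(WedgeSpec(start_angle=cursor, end_angle=cursor + arc, fill=fill))
        cursor += arc
    return PieGlyph(center=(x, y), radius=comp.radius, wedges=tuple(wedges))


# ---------------------------------------------------------------------------
# Output


def _rgb_hex(color: RGB) -> str:
    r, g, b = (max(0, min(255, round(c * 255))) for c in color)
    return f"#{r:02x}{g:02x}{b:02x}"


def _fmt(v: float) -> str:
    return f"{v:.3f}"


class _DataToScreen:
    """Uniform (aspect-preserving) data -> pixel mapping with y flip."""

    def __init__(
        self, glyphs: Sequence[PieGlyph], plot_w: float, plot_h: float, pad: float = 10.0
    ) -> None:
        xs = np.array([g.center[0] for g in glyphs])
        ys = np.array([g.center[1] for g in glyphs])
        rs = np.array([g.radius for g in glyphs])
        x_lo, x_hi = float((xs - rs).min()), float((xs + rs).max())
        y_lo, y_hi = float((ys - rs).min()), float((ys + rs).max())
        span_x = max(x_hi - x_lo, 1e-12)
        span_y = max(y_hi - y_lo, 1e-12)
        self.scale = min((plot_w - 2 * pad) / span_x, (plot_h - 2 * pad) / span_y)
        # center the data block inside the plot area
        self.x_off = (plot_w - self.scale * span_x) / 2.0 - self.scale * x_lo
        self.y_off = (plot_h - self.scale * span_y) / 2.0 + self.scale * y_hi

    def point(self, x: float, y: float) -> tuple[float, float]:
        return self.scale * x + self.x_off, -self.scale * y + self.y_off

    def length(self, r: float) -> float:
        return self.scale * r


def _wedge_path(cx: float, cy: float, r: float, wedge: WedgeSpec) -> str:
    """SVG path for a wedge, clockwise from 12 o'clock, in screen coords."""
    a0 = math.radians(wedge.start_angle)
    a1 = math.radians(wedge.end_angle)
    x0, y0 = cx + r * math.sin(a0), cy - r * math.cos(a0)
    x1, y1 = cx + r * math.sin(a1), cy - r * math.cos(a1)
    large = 1 if wedge.arc > 180.0 else 0
    return (
        f'<path d="M {_fmt(cx)} {_fmt(cy)} L {_fmt(x0)} {_fmt(y0)} '
        f"A {_fmt(r)} {_fmt(r)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)} Z\" "
        f'fill="{_rgb_hex(wedge.fill)}"/>'
    )


def _legend_svg(
    legend: Sequence[LegendEntry], x0: float, width: float, height: float, max_rows: int
) -> list[str]:
    if not legend:
        return []
    line_h, swatch, font = 14.0, 9.0, 10
    n_cols = max(1, math.ceil(len(legend) / max_rows))
    rows = math.ceil(len(legend) / n_cols)
    col_w = width / n_cols
    parts: list[str] = ['<g font-family="sans-serif" font-size="%d">' % font]
    for i, entry in enumerate(legend):
        col, row = divmod(i, rows)
        x = x0 + col * col_w
        y = 20.0 + row * line_h
        if y > height - 5:
            continue
        if entry.is_header:
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-weight="bold">'
                f"{_escape(entry.label)}</text>"
            )
        else:
            assert entry.color is not None
            parts.append(
                f'<rect x="{_fmt(x)}" y="{_fmt(y - swatch + 1)}" '
                f'width="{_fmt(swatch)}" height="{_fmt(swatch)}" '
                f'fill="{_rgb_hex(entry.color)}"/>'
                f'<text x="{_fmt(x + swatch + 4)}" y="{_fmt(y)}">'
                f"{_escape(entry.label)}</text>"
            )
    parts.append("</g>")
    return parts


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _render_svg(
    glyphs: Sequence[PieGlyph],
    legend: Sequence[LegendEntry],
    config: RenderConfig,
    path: Path,
) -> None:
    w, h = float(config.width), float(config.height)
    plot_w = w * (1.0 - config.legend_fraction)
    tf = _DataToScreen(glyphs, plot_w, h)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{config.width}" '
        f'height="{config.height}" viewBox="0 0 {config.width} {config.height}">',
        f'<rect x="0" y="0" width="{config.width}" height="{config.height}" '
        f'fill="{_rgb_hex(config.background)}"/>',
        "<g>",
    ]
    for glyph in glyphs:
        cx, cy = tf.point(*glyph.center)
        r = tf.length(glyph.radius)
        if glyph.dot_color is not None:
            parts.append(
                f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
                f'fill="{_rgb_hex(glyph.dot_color)}"/>'
            )
            continue
        for wedge in glyph.wedges:
            if wedge.arc >= 360.0 - FULL_CIRCLE_EPS:
                parts.append(
                    f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
                    f'fill="{_rgb_hex(wedge.fill)}"/>'
                )
            else:
                parts.append(_wedge_path(cx, cy, r, wedge))
    parts.append("</g>")
    parts.extend(
        _legend_svg(legend, plot_w + 8.0, w - plot_w - 12.0, h, config.max_legend_rows)
    )
    parts.append("</svg>")
    path.write_text("\n".join(parts) + "\n", encoding="utf-8")


def _render_png(
    glyphs: Sequence[PieGlyph],
    legend: Sequence[LegendEntry],
    config: RenderConfig,
    path: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import pyplot as plt
    from matplotlib.patches import Circle, Wedge

    fig = plt.figure(
        figsize=(config.width / config.dpi, config.height / config.dpi),
        dpi=config.dpi,
        facecolor=config.background,
    )
    try:
        ax = fig.add_axes((0.0, 0.0, 1.0 - config.legend_fraction, 1.0))
        ax.set_axis_off()
        ax.set_aspect("equal")
        for glyph in glyphs:
            cx, cy = glyph.center
            if glyph.dot_color is not None:
                ax.add_patch(Circle((cx, cy), glyph.radius, facecolor=glyph.dot_color, linewidth=0))
                continue
            for wedge in glyph.wedges:
                if wedge.arc >= 360.0 - FULL_CIRCLE_EPS:
                    ax.add_patch(Circle((cx, cy), glyph.radius, facecolor=wedge.fill, linewidth=0))
                else:
                    # matplotlib wedges are counterclockwise from east
                    ax.add_patch(
                        Wedge(
                            (cx, cy),
                            glyph.radius,
                            90.0 - wedge.end_angle,
                            90.0 - wedge.start_angle,
                            facecolor=wedge.fill,
                            linewidth=0,
                        )
                    )
        ax.autoscale_view()
        # legend in the reserved right margin, wrapped into columns
        if legend:
            rows = config.max_legend_rows
            n_cols = max(1, math.ceil(len(legend) / rows))
            rows = math.ceil(len(legend) / n_cols)
            x_base = 1.0 - config.legend_fraction + 0.01
            col_w = (config.legend_fraction - 0.02) / n_cols
            for i, entry in enumerate(legend):
                col, row = divmod(i, rows)
                x = x_base + col * col_w
                y = 0.97 - row * 0.022
                if y < 0.02:
                    continue
                weight = "bold" if entry.is_header else "normal"
                color = "black" if entry.is_header else None
                fig.text(
                    x,
                    y,
                    ("" if entry.is_header else "■ ") + entry.label,
                    fontsize=6,
                    fontweight=weight,
                    color=color if entry.is_header else entry.color,
                    va="top",
                )
        fig.savefig(path, dpi=config.dpi, facecolor=config.background)
    finally:
        plt.close(fig)


def render_figure(
    glyphs: Sequence[PieGlyph],
    legend: Sequence[LegendEntry],
    config: RenderConfig,
    path: str | Path,
) -> None:
    """Write the glyphs and legend as an SVG or PNG figure.

    The data-to-pixel mapping preserves aspect ratio; glyphs are drawn in
    input order. SVG output is byte-deterministic for identical inputs.
    """
    if not glyphs:
        raise ValidationError("nothing to render: zero glyphs")
    path = Path(path)
    if config.out_format == "svg":
        _render_svg(glyphs, legend, config, path)
    else:
        _render_png(glyphs, legend, config, path)
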