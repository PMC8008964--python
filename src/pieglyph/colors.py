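"""Color assignment for genes and intensity-modulated slice colors.

A gene group's color rule is either a single color (every gene in the group
shares it) or the name of a matplotlib colormap, in which case the ``n``
genes of the group sample the *full* map range at positions ``i / (n - 1)``
(a single gene samples position 0). Sampling the full range maximizes
distinguishability for long ordered marker lists (e.g. differentiation
markers sorted early to late).

Rule disambiguation: a string starting with ``#`` is always a hex color;
an exact registered-colormap name is a colormap; anything else is tried as
a named color. To use a color whose name collides with a colormap name
(e.g. ``gray``), give it as hex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import matplotlib
from matplotlib.colors import to_rgb

from .errors import ColormapNotFoundError, ColorParseError
from .io import GeneListSpec

__all__ = [
    "RGB",
    "GroupColorRule",
    "ColorAssignment",
    "LegendEntry",
    "parse_color",
    "assign_colors",
    "apply_intensity",
    "build_legend_entries",
]

RGB = tuple[float, float, float]

WHITE: RGB = (1.0, 1.0, 1.0)


def parse_color(spec: str) -> RGB:
    """Parse ``#RRGGBB`` hex or a named color into an RGB triple in [0,1]."""
    try:
        return tuple(float(c) for c in to_rgb(spec))  # type: ignore[return-value]
    except ValueError as exc:
        raise ColorParseError(f"cannot parse color {spec!r}") from exc


@dataclass(frozen=True)
class GroupColorRule:
    """How one group's colors were derived: a fixed color, or a colormap
    with the sample positions actually used."""

    group: str
    kind: str  # "single" | "colormap"
    rule: str
    positions: tuple[float, ...]  # empty for single-color groups


@dataclass(frozen=True)
class ColorAssignment:
    """Base color per gene plus the per-group rule records."""

    base: Mapping[str, RGB]
    rules: tuple[GroupColorRule, ...]


def _colormap_positions(n: int) -> tuple[float, ...]:
    if n == 1:
        return (0.0,)
    return tuple(i / (n - 1) for i in range(n))


def assign_colors(
    spec: GeneListSpec,
    palette_registry: Mapping[str, object] | None = None,
) -> ColorAssignment:
    """Assign a deterministic base color to every gene in the spec.

    ``palette_registry`` maps colormap names to matplotlib colormaps and
    defaults to ``matplotlib.colormaps``.
    """
    registry = palette_registry if palette_registry is not None else matplotlib.colormaps
    base: dict[str, RGB] = {}
    rules: list[GroupColorRule] = []
    for grp in spec.groups:
        rule = grp.color_rule
        is_hex = rule.startswith("#")
        in_registry = False
        if not is_hex:
            try:
                in_registry = rule in registry
            except TypeError:
                in_registry = False
        if not is_hex and in_registry:
            cmap = registry[rule]
            positions = _colormap_positions(grp.n_genes)
            for gene, pos in zip(grp.genes, positions):
                rgba = cmap(pos)
                base[gene] = (float(rgba[0]), float(rgba[1]), float(rgba[2]))
            rules.append(
                GroupColorRule(group=grp.name, kind="colormap", rule=rule, positions=positions)
            )
        else:
            try:
                color = parse_color(rule)
            except ColorParseError:
                if is_hex:
                    raise
                raise ColormapNotFoundError(
                    f"unknown colormap or color {rule!r} for group {grp.name!r}"
                ) from None
            for gene in grp.genes:
                base[gene] = color
            rules.append(
                GroupColorRule(group=grp.name, kind="single", rule=rule, positions=())
            )
    return ColorAssignment(base=base, rules=tuple(rules))


def apply_intensity(base: RGB, intensity: float, lighten_enabled: bool = True) -> RGB:
    """Interpolate a slice color toward white by (1 - intensity).

    With lightening enabled the returned color is
    ``white + intensity * (base - white)`` per channel: intensity 1 gives the
    base color, intensity 0 gives white, so pale slices mean low expression.
    With lightening disabled the base color is returned unchanged.
    """
    if not (0.0 <= intensity <= 1.0):
        raise ValueError(f"intensity {intensity!r} outside [0, 1]")
    if any(not (0.0 <= c <= 1.0) for c in base):
        raise ValueError(f"base color channels outside [0, 1]: {base!r}")
    if not lighten_enabled:
        return base
    # b*i + (1-i) is algebraically white + i*(base - white) but exact at both
    # endpoints in floating point
    return tuple(b * intensity + (1.0 - intensity) for b in base)  # type: ignore[return-value]


@dataclass(frozen=True)
class LegendEntry:
    """One legend line: a group header (no swatch) or a gene with its
    base-color swatch."""

    label: str
    color: RGB | None
    is_header: bool


def build_legend_entries(
    assignment: ColorAssignment, spec: GeneListSpec
) -> list[LegendEntry]:
    """Gene legend in concatenated list order, grouped under group headers."""
    entries: list[LegendEntry] = []
    for grp in spec.groups:
        entries.append(LegendEntry(label=grp.name, color=None, is_header=True))
        for gene in grp.genes:
            entries.append(
                LegendEntry(label=gene, color=assignment.base[gene], is_header=False)
            )
    return entries
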