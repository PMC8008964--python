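"""Exception hierarchy for pieglyph.

All errors raised by the library derive from :class:`PieGlyphError` so the
CLI can surface them uniformly with a one-line diagnostic.
"""


class PieGlyphError(Exception):
    """Base class for all pieglyph errors."""


class ValidationError(PieGlyphError, ValueError):
    """Input data violates an invariant (negative values, duplicate ids, ...)."""


class FormatError(ValidationError):
    """A file could not be parsed as the expected format."""


class GeneNotFoundError(PieGlyphError, LookupError):
    """A requested gene is absent from the expression matrix."""


class ColormapNotFoundError(PieGlyphError, LookupError):
    """A color rule names a colormap that is not registered."""


class ColorParseError(PieGlyphError, ValueError):
    """A color string could not be parsed."""
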