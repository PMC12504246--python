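"""Exception types shared across the package."""


class HistoAtlasError(Exception):
    """Base class for all errors raised by histoatlas."""


class ValidationError(HistoAtlasError, ValueError):
    """Input data violates a documented invariant (bad hierarchy, degenerate
    anchoring, malformed descriptor, ...)."""


class GeometryError(HistoAtlasError, ValueError):
    """A geometric construction is impossible (collinear points,
    rank-deficient fit, point outside the triangulated hull)."""
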