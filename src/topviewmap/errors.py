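"""Exception types shared across the package."""


class TopViewError(Exception):
    """Base class for all errors raised by topviewmap."""


class GeometryError(TopViewError):
    """Invalid or degenerate geometry (lines, polylines, quadrilaterals)."""


class ValidationError(TopViewError):
    """Input failed a structural validation rule (monotonicity, ranges, labels)."""
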