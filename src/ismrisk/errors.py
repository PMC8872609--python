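"""Exception and warning types shared across the package."""


class IsmRiskError(Exception):
    """Base class for all package errors."""


class FormatError(IsmRiskError, ValueError):
    """Malformed input file: missing columns, bad symbols, ragged tables."""


class ValidationError(IsmRiskError, ValueError):
    """Structurally well-formed input that violates a domain invariant."""


class IsmRiskWarning(UserWarning):
    """Base class for recoverable input anomalies."""


class GlyphSubstitutionWarning(IsmRiskWarning):
    """An SSIM cell used a tolerated variant glyph (digit 0, lower case)."""


class NotClosedWarning(IsmRiskWarning):
    """A matrix passed as final was not transitively closed; the closure is used."""


class ElementMismatchWarning(IsmRiskWarning):
    """SSIM element set differs from the selected key-risk set."""


class SelfLoopWarning(IsmRiskWarning):
    """Adjacency input carried diagonal entries; self-relations are ignored."""
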