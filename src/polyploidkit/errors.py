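"""Exception hierarchy.

All user-facing failures derive from :class:`PolyploidKitError` so the CLI
can map them to exit code 2; programming errors propagate as-is.
"""


class PolyploidKitError(Exception):
    """Base class for all validation / configuration / parse failures."""


class ConfigurationError(PolyploidKitError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(PolyploidKitError):
    """Input data violates a documented contract."""


class ParseError(PolyploidKitError):
    """Malformed on-disk input; message names the file and line."""


class SaturationError(PolyploidKitError):
    """Observed divergence beyond the domain of the distance correction."""


class UndefinedDistanceError(PolyploidKitError):
    """A pairwise distance with zero comparable sites."""
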