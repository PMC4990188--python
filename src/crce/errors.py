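"""Exception types shared across the package."""


class CRCEError(Exception):
    """Base class for all crce-specific errors."""


class SchemaError(CRCEError):
    """A required column is missing or unresolvable in an input table."""


class ConsistencyError(CRCEError):
    """The table violates a design invariant (e.g. one plot, two treatments)."""


class DegenerateFitError(CRCEError):
    """The compensation-line regression cannot be fit (zero variance in CE)."""


class UndefinedEffectError(CRCEError):
    """A log response ratio is requested for a nonpositive mean richness."""
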