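"""Exception hierarchy for model and data-validation failures."""


class ThromboflapError(Exception):
    """Base class for all package-specific errors."""


class EmptyRegistryError(ThromboflapError):
    """Raised when a registry summary is requested on zero records."""


class ValidationError(ThromboflapError):
    """Raised when an input violates a declared range or invariant."""


class InfeasibleParametersError(ThromboflapError):
    """Raised when no baseline risk can balance the observed complication rate."""


class NoBreakEvenError(ThromboflapError):
    """Raised when a scenario averts no complications relative to baseline."""
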