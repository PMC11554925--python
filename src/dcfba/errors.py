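"""Exception hierarchy shared across the package."""


class DcfbaError(Exception):
    """Base class for all package-specific errors."""


class ModelError(DcfbaError):
    """Structural problem in a metabolic network (bad bounds, missing biomass, ...)."""


class EditError(DcfbaError):
    """Genotype edit refers to unknown reactions or collides with existing ids."""


class FeasibilityError(DcfbaError):
    """An LP/NLP has no feasible point under the requested constraints."""

    def __init__(self, message, violated=None):
        super().__init__(message)
        self.violated = violated or {}


class UnboundedError(DcfbaError):
    """LP objective is unbounded in the requested sense."""


class DomainError(DcfbaError):
    """Argument outside the mathematical domain (e.g. mu outside the envelope)."""


class InsufficientDataError(DcfbaError):
    """Too few samples to fit the requested quantity."""


class DataError(DcfbaError):
    """Malformed or physically impossible input data."""


class ConfigError(DcfbaError):
    """Invalid run configuration."""
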