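"""Exception hierarchy for the biomass-estimation pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2,
ConfigurationError -> 3, I/O problems -> 4.
"""


class SavannaAgbError(Exception):
    """Base class for all package errors."""


class ValidationError(SavannaAgbError):
    """A record violates a domain invariant."""


class UnclassifiableError(ValidationError):
    """An individual cannot be assigned a growth class.

    Carries the list of missing fields that would be needed.
    """

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class FormatError(SavannaAgbError):
    """An input table does not match the expected schema."""


class ConfigurationError(SavannaAgbError):
    """Missing or inconsistent configuration (calibration, areas, strata)."""


class InsufficientDataError(ConfigurationError):
    """Too few usable observations to perform a requested fit."""


class SingularFitError(ConfigurationError):
    """The requested regression is degenerate (no variation in the predictor)."""


class EstimationError(SavannaAgbError):
    """An individual lacks the proxies required by its dispatched workflow."""


class SwdLookupError(EstimationError):
    """No wood-density value resolvable for a species (no fallback available)."""
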