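"""Exception types shared across the package."""


class AdosimError(Exception):
    """Base class for package-specific errors."""


class DomainError(AdosimError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(AdosimError, ValueError):
    """Incompatible or incomplete configuration of beliefs, foci, or studies."""


class ImpossibleObservationError(AdosimError, ValueError):
    """A response with zero marginal probability under the current belief."""
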