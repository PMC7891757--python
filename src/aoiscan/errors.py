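"""Exception hierarchy shared across the package."""


class AoiscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AoiscanError, ValueError):
    """Invalid world-model or pipeline configuration."""


class InputError(AoiscanError, ValueError):
    """Malformed or out-of-contract input data."""


class UnknownAOIError(AoiscanError, KeyError):
    """An AOI id was requested that the world model does not define."""


class DegenerateInputError(AoiscanError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero
    variance in a channel that must be standardized, or a reducible chain
    where an irreducible one is required)."""


class StratificationError(AoiscanError, ValueError):
    """A class is too small for the requested stratified fold layout."""
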