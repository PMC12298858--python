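"""Exception hierarchy shared across the pipeline stages."""


class BarcodegapError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(BarcodegapError):
    """Malformed FASTA input; message names the offending line."""


class ValidationError(BarcodegapError):
    """Input violates a documented invariant (duplicate ids, orphans, ...)."""


class ConfigError(BarcodegapError):
    """Invalid configuration value."""


class EstimationError(BarcodegapError):
    """A statistical quantity cannot be estimated from the given data."""


class GapNotFoundError(BarcodegapError):
    """No qualifying empty run in the identity histogram search window."""
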