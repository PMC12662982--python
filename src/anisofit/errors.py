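"""Exception hierarchy shared by all modules."""


class AnisofitError(Exception):
    """Base class for all package errors."""


class FormatError(AnisofitError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(AnisofitError):
    """A record violates a domain invariant (bad sigma, duplicate key, ...)."""


class DataCompletenessError(AnisofitError):
    """Required geometry/shielding/energy records are missing for a fit."""


class UnderDeterminedError(AnisofitError):
    """Fewer observations than the five independent tensor components."""


class ProtocolError(AnisofitError):
    """Configurations being compared were not given identical experimental data."""
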