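"""Exception types shared across the package."""


class PopsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PopsError):
    """A configuration (distribution spec, criterion, model wiring) is invalid."""


class NumericError(PopsError):
    """A numerical routine (ODE solver, covariance factorisation) failed."""


class EngineError(PopsError):
    """A simulation replicate failed; the run is aborted rather than patched."""
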