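"""Exception types shared across the package."""


class ManucountError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(ManucountError, ValueError):
    """A sensor log or frame violates the input contract (missing channel,
    non-monotone time, unparseable row)."""


class ConfigurationError(ManucountError, ValueError):
    """Parameters are inconsistent with each other or with the sampling
    setup (e.g. cutoff at or above Nyquist, calibration/threshold mismatch,
    empty parameter grid)."""


class InsufficientDataError(ManucountError, ValueError):
    """Not enough usable data to estimate a quantity (e.g. too few
    same-direction runs during noise calibration)."""
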