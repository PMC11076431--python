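"""Exception types shared across the package."""


class InvalidSpecError(ValueError):
    """A parameter specification violates its physical constraints."""


class NonPhysicalSignalError(ValueError):
    """Measured signals are inconsistent with the SPGR signal model."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistical operation."""


class UndefinedParameterError(ValueError):
    """A kinetic parameter cannot be computed from the given curve."""
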