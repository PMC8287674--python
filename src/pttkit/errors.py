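"""Exception hierarchy shared across the toolkit."""


class PTTKitError(Exception):
    """Base class for all toolkit errors."""


class DomainError(PTTKitError, ValueError):
    """A scalar argument violates its physical domain (e.g. tau <= 0)."""


class DegenerateTraceError(PTTKitError, ValueError):
    """A temperature trace carries no usable thermal signal (T_max == T_surr)."""


class InsufficientDataError(PTTKitError, ValueError):
    """Too few usable points for the requested fit."""


class NonCoolingTraceError(PTTKitError, ValueError):
    """The cooling-phase regression produced a non-positive time constant."""


class InvalidAssayError(PTTKitError, ValueError):
    """Assay controls are inconsistent (e.g. positive control <= negative)."""


class RankDeficiencyError(PTTKitError, ValueError):
    """Calibration design is rank deficient (a single distinct concentration)."""


class SchemaError(PTTKitError, ValueError):
    """An input file does not match its declared schema."""
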