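"""Exception hierarchy for the freezekin pipeline."""


class FreezekinError(Exception):
    """Base class for all freezekin errors."""


class FormatError(FreezekinError):
    """A file does not conform to the expected layout (missing column, bad header)."""


class DataError(FreezekinError):
    """Data content violates an invariant (non-finite, non-monotone time, bad quaternion)."""


class ParameterError(FreezekinError):
    """An argument is outside its valid domain."""


class NoStridesFound(DataError):
    """No usable gait cycles could be delimited in the signal."""


class ZuptImpossible(DataError):
    """Zero-velocity updates cannot be applied (no flat-foot intervals)."""


class GateError(ParameterError):
    """Normality gating cannot be run (degenerate or undersized group)."""


class AlignmentError(DataError):
    """IMU and reference stride segmentations cannot be paired."""
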