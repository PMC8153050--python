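"""Exception types shared across the pipeline stages."""


class UrgewaveError(Exception):
    """Base class for all package errors."""


class ParameterError(UrgewaveError, ValueError):
    """A parameter violates its documented constraint."""


class DegenerateInputError(UrgewaveError, ValueError):
    """Input is structurally valid but statistically degenerate
    (zero variance, empty class, constant curve, ...)."""


class EdgeContaminationError(UrgewaveError, ValueError):
    """Epoch padding is too short for the requested wavelet lengths."""


class EmptyEpochSetError(UrgewaveError, ValueError):
    """No events survived epoching."""


class NoOnsetError(DegenerateInputError):
    """The curve never exceeds the onset criterion."""


class InsufficientSegmentError(DegenerateInputError):
    """A segment is too short for the requested fit."""
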