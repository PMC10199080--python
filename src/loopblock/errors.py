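"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(RuntimeError):
    """Not enough valid observations to compute the requested quantity."""


class UndefinedMeasurementError(RuntimeError):
    """The measurement is mathematically undefined for this input (e.g. zero total intensity)."""


class OutOfFieldError(ValueError):
    """A position or polyline falls outside the image field of view."""


class MissingMetadataError(IOError):
    """A movie file lacks spatial/temporal calibration and no override was supplied."""
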