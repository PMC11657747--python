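"""Exception hierarchy shared across the package."""


class SparseCNVError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SparseCNVError, ValueError):
    """An argument violated a documented precondition."""


class ParseError(SparseCNVError, ValueError):
    """A text input could not be parsed; the message names the offending line."""


class FormatError(SparseCNVError, ValueError):
    """An on-disk artifact is internally inconsistent (e.g. sidecar length mismatch)."""


class ShapeError(SparseCNVError, ValueError):
    """Array dimensions do not agree with the coordinate frame."""


class KneeNotFoundError(SparseCNVError, RuntimeError):
    """The barcode rank curve has no detectable knee; use the fixed-cutoff method."""


class ConfigurationError(SparseCNVError, ValueError):
    """A run configuration is incomplete or inconsistent."""
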