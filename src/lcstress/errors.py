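"""Exception types shared across the pipeline."""


class LcstressError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LcstressError, ValueError):
    """A parameter violates an operation's precondition."""


class DegenerateDesignError(LcstressError):
    """A regression design is rank deficient or otherwise unusable."""


class InsufficientDataError(LcstressError):
    """Not enough usable observations (e.g. a missing condition)."""


class InvalidMaskError(LcstressError):
    """A probabilistic mask has no positive weight or wrong grid."""


class GridMismatchError(LcstressError):
    """Data and mask are not defined on the same voxel grid."""
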