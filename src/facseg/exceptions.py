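"""Exception hierarchy for facseg."""


class FacsegError(Exception):
    """Base class for all facseg errors."""


class ParameterError(FacsegError, ValueError):
    """A model or kernel parameter is outside its valid range."""


class DegeneratePartitionError(FacsegError):
    """The membership map gives zero total weight to one of the two regions,
    so a region prototype is undefined."""


class DegenerateUpdateError(FacsegError):
    """A candidate membership update would drive an energy-difference
    denominator non-positive; the update must be rejected."""


class UndefinedScoreError(FacsegError, ValueError):
    """Segmentation accuracy is undefined (both masks empty)."""
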