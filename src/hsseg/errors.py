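"""Exception hierarchy used across the package.

All hsseg errors derive from :class:`HssegError`; the concrete classes also
derive from ``ValueError`` so callers that do not care about the distinction
can catch the built-in.
"""


class HssegError(Exception):
    """Base class for all hsseg-specific errors."""


class ConfigError(HssegError, ValueError):
    """A parameter value violates its contract (bad mask size, threshold, ...)."""


class FormatError(HssegError, ValueError):
    """An on-disk file does not match its declared layout (size, dtype, ...)."""


class DimensionError(HssegError, ValueError):
    """Array shapes or lengths that must agree do not."""


class RangeError(HssegError, ValueError):
    """Values fall outside the range an operation requires (e.g. not in [0, 1])."""


class DegenerateInputError(HssegError, ValueError):
    """Input is structurally unusable: monotone reference curve, fewer
    distinct feature vectors than requested classes, empty ROI, ..."""


class UndefinedScoreError(HssegError, ValueError):
    """A confusion-matrix score is undefined because a class is empty."""
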