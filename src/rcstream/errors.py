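"""Exception hierarchy for rcstream.

Every error raised by the package derives from :class:`RcStreamError` so
callers can catch the whole family; subclasses distinguish configuration
mistakes from data problems.
"""


class RcStreamError(Exception):
    """Base class for all rcstream errors."""


class ConfigurationError(RcStreamError, ValueError):
    """A configuration value is invalid; the message names the field."""


class CalibrationError(RcStreamError, ValueError):
    """Amplifier-calibration or gain-calibration input is unusable."""


class DecodeError(RcStreamError, KeyError):
    """A coded settings value is absent from the codebook."""


class JSONRepairError(RcStreamError, ValueError):
    """Malformed JSON text cannot be balanced by appending closers.

    Carries ``offset``, the byte offset of the first unbalanceable token.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class EmptySessionError(RcStreamError):
    """No stream in the session folder was usable."""


class EmptyStreamError(RcStreamError):
    """An operation that needs samples received an empty stream."""


class AlignmentError(RcStreamError):
    """Two samples of one stream claimed the same grid point."""


class UsageError(RcStreamError):
    """An operation was applied outside its stated domain."""


class InsufficientDataError(RcStreamError):
    """Not enough continuous data for the requested analysis."""


class StoreError(RcStreamError):
    """A persisted stream store is unreadable or corrupt."""


class StoreVersionError(StoreError):
    """A persisted stream store was written by an incompatible version."""


class SessionOverlapError(RcStreamError):
    """Two sessions to be concatenated overlap in time."""
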