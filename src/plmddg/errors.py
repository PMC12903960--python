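"""Exception hierarchy shared across the toolkit.

Every error raised by plmddg derives from :class:`PlmDdgError`, so callers
(and the CLI) can distinguish tool errors from programming errors.
"""


class PlmDdgError(Exception):
    """Base class for all plmddg errors."""


class TableFormatError(PlmDdgError):
    """A mutation table is structurally malformed (e.g. missing columns)."""


class RecordValueError(PlmDdgError):
    """A table row carries an unparseable or out-of-vocabulary value."""


class SequenceMismatchError(PlmDdgError):
    """The declared wild-type residue disagrees with the chain sequence."""


class PositionRangeError(PlmDdgError):
    """A mutation position falls outside the associated sequence."""


class ConfigurationError(PlmDdgError):
    """An invalid parameter combination (k too large, even window, ...)."""


class UsageError(PlmDdgError):
    """An operation was applied to inputs it is not meant for
    (double augmentation, mutating to the existing residue, ...)."""


class ShapeError(PlmDdgError):
    """Array dimensions disagree with the declared contract."""


class CapabilityError(PlmDdgError):
    """A backend or feature is unavailable in this installation."""


class CacheIntegrityError(PlmDdgError):
    """A cache entry exists but cannot be read back consistently."""


class CompatibilityError(PlmDdgError):
    """A checkpoint's stored configuration disagrees with the caller's."""


class LeakageError(PlmDdgError):
    """Train and test partitions share complexes."""


class LookupError_(PlmDdgError):
    """A required sequence or embedding is missing for a record."""
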