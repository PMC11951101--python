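"""Exception hierarchy for the repertoire pipeline.

Every error raised by this package derives from :class:`BcrPipeError`, so
callers can catch pipeline failures without masking programming errors.
"""


class BcrPipeError(Exception):
    """Base class for all package errors."""


class FormatError(BcrPipeError):
    """A file does not conform to its declared format (missing columns,
    malformed lines)."""


class RecordValidationError(BcrPipeError):
    """One or more records violate a structural invariant (e.g. alignment
    length mismatch).  Carries the per-row rejection report."""

    def __init__(self, message, rejections=None):
        super().__init__(message)
        self.rejections = list(rejections or [])


class DegenerateAlignmentError(BcrPipeError):
    """An alignment has no comparable (unambiguous, ungapped) positions."""


class CalibrationError(BcrPipeError):
    """Too few calibration chains to estimate the naive mutation threshold."""


class InsufficientDataError(BcrPipeError):
    """A statistic was requested on too little data (empty group, n below
    the documented floor)."""


class UndefinedStatisticError(BcrPipeError):
    """The requested statistic is undefined on the data (e.g. Pearson r with
    zero variance)."""


class CrossDonorError(BcrPipeError):
    """A within-donor quantity was requested across donors; clonotype sharing
    is only meaningful inside one individual's repertoire."""


class PairingError(BcrPipeError):
    """Paired test requested but the two groups cannot be matched one-to-one
    on the pairing key."""

    def __init__(self, message, unmatched=None):
        super().__init__(message)
        self.unmatched = list(unmatched or [])


class ScoringError(BcrPipeError):
    """Signature scoring could not proceed (gene set absent from matrix)."""


class DepthError(BcrPipeError):
    """Rarefaction depth exceeds the number of available cells."""


class ConfigError(BcrPipeError):
    """Synthetic-cohort configuration is internally inconsistent."""
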