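"""Exception hierarchy used across the pipeline.

Validation errors signal malformed inputs (wrong columns, out-of-range
values); the remaining classes mark well-defined analytic failure modes so
callers can distinguish "bad file" from "the data do not support this step".
"""


class PanFFPEError(Exception):
    """Base class for all pipeline errors."""


class DialectError(PanFFPEError):
    """A table does not match the expected column dialect."""


class ValidationError(PanFFPEError):
    """A value violates a domain invariant (negative TIC, probability > 1, ...)."""


class NoDataError(PanFFPEError):
    """An operation was asked for data that does not exist (e.g. no MS1 scans)."""


class DegenerateDesignError(PanFFPEError):
    """A regression design is singular (e.g. all calibration amounts identical)."""


class CalibrationRejectedError(PanFFPEError):
    """A calibration curve failed its QC gate and must not be used downstream."""


class NoKneeError(PanFFPEError):
    """No completeness cutoff satisfies the second-derivative tolerance."""


class StratificationError(PanFFPEError):
    """A cohort is too small to be split into two balanced halves."""


class InsufficientStandardsError(PanFFPEError):
    """Too few retention-time standards matched to fit a drift model."""
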