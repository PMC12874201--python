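"""Typed errors raised across the pipeline.

Each stage raises a subclass of :class:`LsprKinError` so callers can
distinguish bad inputs (``DomainError``), missing data
(``MissingReferenceError``), and numerical failures (``FitConvergenceError``).
"""


class LsprKinError(Exception):
    """Base class for all package errors."""


class DomainError(LsprKinError, ValueError):
    """An argument is outside the physical domain (negative time, rate, ...)."""


class MissingReferenceError(LsprKinError):
    """Reference-channel operation requested on a single-channel sensorgram."""


class GridMismatchError(LsprKinError):
    """Active and reference channels do not share the same time grid."""


class DegenerateDataError(LsprKinError):
    """Data carry no information for the requested fit (e.g. constant signal)."""


class FitConvergenceError(LsprKinError):
    """Nonlinear least squares failed to converge.

    Carries solver diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class BasisError(LsprKinError):
    """Concentration-basis mismatch (monomeric vs polymeric) in a conversion."""


class CsvFormatError(LsprKinError):
    """Sensorgram CSV violates the dialect; message names the offending line."""


class PipelineError(LsprKinError):
    """A pipeline stage failed; ``stage`` identifies where."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
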