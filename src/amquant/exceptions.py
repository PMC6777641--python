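"""Exception hierarchy for :mod:`amquant`.

All package errors derive from :class:`AMQuantError` so callers (notably the
CLI) can distinguish data problems from programming errors.
"""

from __future__ import annotations


class AMQuantError(Exception):
    """Base class for all amquant errors."""


class SchemaError(AMQuantError):
    """The table header does not match the expected input dialect."""


class DataValidationError(AMQuantError):
    """Cell-level validation failed; carries the full validation report."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class ScoreError(AMQuantError):
    """A colonization score code does not match the score grammar."""


class InferenceError(AMQuantError):
    """A statistical routine was called on unusable data."""


class PlotError(AMQuantError):
    """Figure construction or export failed."""


class SimulationError(AMQuantError):
    """Invalid simulation parameters."""
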