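"""Exception hierarchy.

All package errors derive from :class:`MeiocoError` so callers (and the CLI)
can map them onto exit codes: validation problems are user-input faults,
everything else is a runtime fault.
"""

from __future__ import annotations


class MeiocoError(Exception):
    """Base class for all errors raised by meioco."""


class ValidationError(MeiocoError):
    """Input data violates a documented invariant."""


class FocusTableError(ValidationError):
    """One or more rows of a focus-map table failed validation.

    Carries every per-row diagnostic so a malformed file is reported in a
    single pass rather than one row at a time.
    """

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = list(diagnostics)
        preview = "\n  ".join(self.diagnostics[:20])
        more = "" if len(self.diagnostics) <= 20 else f"\n  ... {len(self.diagnostics) - 20} more"
        super().__init__(f"{len(self.diagnostics)} invalid row(s):\n  {preview}{more}")


class FormatError(ValidationError):
    """A table is structurally unreadable (missing columns, bad header)."""


class ConfigurationError(MeiocoError):
    """A parameter combination cannot be satisfied (e.g. interval-count rule
    applied to a class with no inter-focus gaps)."""


class SimulationError(MeiocoError):
    """The generative model could not produce a sample (e.g. obligate-CO
    rejection cap exceeded because the expected event count is far below 1)."""


class FitError(MeiocoError):
    """An estimator had too little or degenerate data to produce a fit."""


class DegenerateDataError(MeiocoError):
    """A statistic is undefined on this input (zero variance, constant groups)."""
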