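"""Exception hierarchy for survey validation, configuration and numerics."""


class LimnoError(Exception):
    """Base class for all package errors."""


class SurveyFormatError(LimnoError):
    """The survey file cannot be parsed at all (missing header, wrong columns)."""


class SurveyValidationError(LimnoError):
    """One or more rows violate the monitoring-record invariants.

    Carries the full list of row-level diagnostics so no violation is
    silently dropped.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        msg = "; ".join(self.diagnostics[:10])
        if len(self.diagnostics) > 10:
            msg += f"; ... ({len(self.diagnostics)} problems total)"
        super().__init__(f"survey validation failed: {msg}")


class StandardsConfigError(LimnoError):
    """The evaluation-standards configuration is malformed or inconsistent."""


class DomainError(LimnoError):
    """A scalar input lies outside the physically meaningful domain."""


class DegenerateInputError(LimnoError):
    """The input is structurally valid but statistically degenerate
    (zero variance, empty record, non-positive denominator)."""
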