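"""Exception hierarchy.

Each error class carries a distinct process exit code so the CLI can signal
schema problems, fit failures and design-estimability failures separately.
"""


class QpopError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(QpopError):
    """Invalid domain object or argument (bad levels, size mismatches...)."""

    exit_code = 2


class SchemaError(QpopError):
    """Malformed input file; message names the offending cell/column."""

    exit_code = 2


class DesignError(QpopError):
    """Unsupported or unconstructible experimental design."""

    exit_code = 4


class EstimabilityError(QpopError):
    """Model matrix rank-deficient; message lists confounded terms."""

    exit_code = 4


class FitError(QpopError):
    """Nonlinear fit failed to converge; best attempt attached."""

    exit_code = 3

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt
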