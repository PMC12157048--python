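"""Exception hierarchy shared across the package."""


class UsfoldError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(UsfoldError, ValueError):
    """An input violates a documented precondition; the message names the field."""


class DegenerateInputError(UsfoldError, ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class CollinearityError(UsfoldError, ValueError):
    """A regression design matrix is rank deficient; the message names the columns."""


class NoSolutionError(UsfoldError, RuntimeError):
    """An iterative search exhausted its cap without reaching the target."""


class ConfigValidationError(UsfoldError, ValueError):
    """A configuration object is invalid; carries every violation at once."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration: " + "; ".join(self.violations)
        )
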