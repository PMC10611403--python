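"""Exception hierarchy used across the package."""


class MMJiveError(Exception):
    """Base class for all package errors."""


class InputError(MMJiveError):
    """A required input (file, column) is missing or unreadable."""


class ValidationError(MMJiveError):
    """Input data violates a structural invariant of the panel model."""


class ConfigError(MMJiveError):
    """A configuration value is inconsistent with the data or other settings."""


class SpecError(MMJiveError):
    """A simulation specification is infeasible."""


class ConvergenceError(MMJiveError):
    """An iterative fit did not converge within its iteration cap."""

    def __init__(self, message: str, last_delta: float | None = None):
        super().__init__(message)
        self.last_delta = last_delta
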