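"""Exception hierarchy for smrbias.

Everything derives from :class:`SMRBiasError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
pipeline stages (configuration, generation, calibration, coverage, the
misclassification algebra).
"""


class SMRBiasError(Exception):
    """Base class for all smrbias errors."""


class ConfigurationError(SMRBiasError, ValueError):
    """Invalid configuration (empty grids, misaligned cut-offs, bad ranges)."""


class InputError(SMRBiasError, ValueError):
    """Invalid input data (inconsistent individuals or stratum tables)."""


class GenerationError(SMRBiasError, RuntimeError):
    """Cohort generation failed (e.g. an individual left reference coverage)."""


class ReferenceCoverageError(SMRBiasError, KeyError):
    """A cohort stratum has no matching reference stratum."""

    def __init__(self, age_group: str, calendar_year: int):
        self.age_group = age_group
        self.calendar_year = calendar_year
        super().__init__(
            f"no reference stratum for age group {age_group!r}, "
            f"calendar year {calendar_year}"
        )


class CalibrationError(SMRBiasError, RuntimeError):
    """Cohort calibration did not converge; carries the residuals."""

    def __init__(self, message: str, residuals: dict | None = None):
        self.residuals = residuals or {}
        if self.residuals:
            message = f"{message} (relative residuals: {self.residuals})"
        super().__init__(message)


class NonInvertibleError(SMRBiasError, ZeroDivisionError):
    """SE + SP = 1: the misclassification correction is undefined."""


class DomainError(SMRBiasError, ValueError):
    """A quantity left its mathematical domain (e.g. expected deaths <= 0)."""


class MisclassificationError(SMRBiasError, ValueError):
    """Corrected counts out of range in strict (non-clamping) mode."""

    def __init__(self, message: str, strata: list | None = None):
        self.strata = strata or []
        if self.strata:
            message = f"{message}: {self.strata}"
        super().__init__(message)
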