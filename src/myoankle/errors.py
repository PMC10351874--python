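"""Exception hierarchy for the myoankle pipeline."""


class MyoankleError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MyoankleError, ValueError):
    """An input violates a documented precondition."""


class IdentifierError(MyoankleError, KeyError):
    """Unknown muscle or feature name."""


class WindowTooShortError(ValidationError):
    """Signal shorter than one analysis window, or window below 2 samples."""


class SchemaError(MyoankleError):
    """A file is missing a required column or sidecar field."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"missing or invalid field: {field!r}")


class AlignmentError(ValidationError):
    """Feature window times fall outside the mechanical time span."""


class CycleError(ValidationError):
    """A gait cycle is incomplete or too short to resample."""


class ContractError(MyoankleError):
    """Prediction-time input does not match the trained model's contract."""


class UndefinedCorrelationError(MyoankleError):
    """Pearson r is undefined (constant reference signal).

    Carries the RMSE, which is still well defined, as ``rmse``.
    """

    def __init__(self, rmse: float):
        self.rmse = rmse
        super().__init__(
            f"Pearson r undefined for a constant reference signal (RMSE={rmse:g})"
        )


class EmptySelectionError(MyoankleError):
    """No combination satisfies a variation-selection filter.

    ``audit`` records every filter step taken before exhaustion.
    """

    def __init__(self, which: str, audit: dict):
        self.which = which
        self.audit = audit
        super().__init__(f"no combination satisfies the {which} selection filters")


class DegenerateCohortError(ValidationError):
    """A cohort RMSE peak is zero, so peak normalization is undefined."""
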