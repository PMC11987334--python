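"""Typed exceptions used across the pipeline.

Every stage raises a narrow exception type so the orchestrator can report
which contract was violated (geometry, schema, calibration, ...) instead of
surfacing a bare ValueError.
"""


class FibroscoreError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FibroscoreError, ValueError):
    """A parameter violates its documented precondition."""


class GeometryError(FibroscoreError):
    """Image/mask/patch dimensions are inconsistent or too small."""


class SchemaError(FibroscoreError):
    """A table or mask carries labels/columns outside the documented schema."""


class CalibrationError(FibroscoreError):
    """Spatial calibration (microns per pixel) is missing and not overridden."""


class NoDermisError(FibroscoreError):
    """The mask contains no position where a full patch fits inside dermis."""


class SamplingExhaustedError(FibroscoreError):
    """Rejection sampling hit its draw cap before placing all patches."""

    def __init__(self, placed: int, requested: int, cap: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed}/{requested} patches before exhausting "
            f"{cap} candidate draws; dermis too small or fragmented"
        )


class JoinError(FibroscoreError):
    """Biopsies could not be joined to labels/predictors by id."""


class ShapeError(FibroscoreError):
    """Array dimensions do not match the fitted model / paired input."""


class NumericError(FibroscoreError):
    """A non-finite value appeared where the contract requires finite output."""


class SeparationError(FibroscoreError):
    """Complete or quasi-separation: the ordinal/logistic MLE diverges."""


class DegenerateAgreementError(FibroscoreError):
    """Both raters constant and identical: expected agreement is 1, kappa undefined."""


class ConfigError(FibroscoreError):
    """Run configuration contains unknown keys or out-of-range values."""
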