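"""Exception hierarchy.

Validation problems (bad shapes, missing structures, impossible parameters)
raise subclasses of :class:`ValidationError`; failures of the method's own
assumptions on otherwise well-formed data (e.g. a unimodal intensity sample)
raise subclasses of :class:`ComputationError`.  The CLI maps the two branches
to distinct exit codes.
"""


class ThighCompError(Exception):
    """Base class for all package errors."""


class ValidationError(ThighCompError):
    """Input failed validation before any computation."""


class GeometryError(ValidationError):
    """Invalid polygon/ROI geometry (overlap, outside bounds, degenerate)."""


class ModelError(ValidationError):
    """Invalid intensity/effect model parameters (e.g. fat mean <= muscle mean)."""


class DesignError(ValidationError):
    """Invalid cohort or study design (e.g. non-positive group size)."""


class InputError(ValidationError):
    """Malformed numeric input (shape mismatch, non-finite, wrong sign)."""


class NamingError(ValidationError):
    """Unknown structure name."""

    def __init__(self, name, valid):
        self.name = name
        self.valid = sorted(valid)
        super().__init__(f"unknown structure {name!r}; valid names: {', '.join(self.valid)}")


class AggregationError(ValidationError):
    """A muscle-group aggregate is missing one of its member muscles."""


class ConfigError(ValidationError):
    """Run configuration invalid (missing path, bad schema)."""


class ComputationError(ThighCompError):
    """The method's assumptions failed on otherwise valid input."""


class NoSignalError(ComputationError):
    """All pixels below the signal threshold; nothing to fit."""


class BimodalityError(ComputationError):
    """Intensity sample is not bimodal; no threshold can be isolated."""


class UndefinedContentError(ComputationError):
    """IntraMAT content undefined (muscle and IntraMAT volumes both zero)."""


class InsufficientDataError(ComputationError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(ComputationError):
    """Correlation undefined (at least one input is constant)."""
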