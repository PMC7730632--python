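"""Exception hierarchy shared by all pipeline stages.

Each class carries the exit code the command-line layer maps it to:
0 ok, 2 validation/format/geometry, 3 detection, 4 signal, 5 fit/evaluation.
"""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class FormatError(PipelineError):
    """A file does not follow the documented on-disk layout."""

    exit_code = 2


class ValidationError(PipelineError):
    """An in-memory object violates its invariants."""

    exit_code = 2


class GeometryError(ValidationError):
    """A rectangle/grid construction produced an empty or inverted region."""


class SceneError(ValidationError):
    """A synthetic scene definition is internally inconsistent."""


class DetectionError(PipelineError):
    """Body or landmark detection found nothing usable."""

    exit_code = 3


class SignalError(PipelineError):
    """A waveform is unusable (all-invalid units, no breaths, ...)."""

    exit_code = 4


class FitError(PipelineError):
    """Calibration regression cannot be fitted."""

    exit_code = 5


class EvaluationError(PipelineError):
    """Agreement statistics cannot be computed (no matched breaths, ...)."""

    exit_code = 5
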