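"""Exception hierarchy for the segmentation pipeline.

Every stage raises a subclass of :class:`SuvsegError` carrying a ``stage``
tag so the CLI can report which pipeline stage failed and exit with a
stage-coded status.
"""


class SuvsegError(Exception):
    """Base class for all pipeline errors."""

    #: pipeline stage the error belongs to; set on subclasses or instances
    stage: str = "pipeline"
    #: CLI exit status associated with the stage
    exit_code: int = 1


class ParameterError(SuvsegError):
    """A configuration or generator parameter is out of its valid range."""

    stage = "config"
    exit_code = 2


class InputError(SuvsegError):
    """An input file is missing, unreadable, or malformed."""

    stage = "input"
    exit_code = 2


class DegenerateInputError(SuvsegError):
    """The input raster carries no usable contrast (e.g. constant image)."""

    stage = "preprocess"
    exit_code = 3


class EmptyMaskError(SuvsegError):
    """A stage that requires a nonempty mask received or produced none."""

    stage = "preprocess"
    exit_code = 3


class InvalidDistributionError(SuvsegError):
    """A probability vector has negative entries or does not sum to one."""

    stage = "entropy"
    exit_code = 4


class EmptyRegionError(SuvsegError):
    """A region statistic was requested on an empty pixel set."""

    stage = "entropy"
    exit_code = 4


class EvolutionCollapsedError(SuvsegError):
    """The zero level set vanished: the contour collapsed or filled the grid."""

    stage = "evolve"
    exit_code = 5


class NumericalBlowupError(SuvsegError):
    """The level set or its energy became non-finite."""

    stage = "evolve"
    exit_code = 5


class UndefinedMetricError(SuvsegError):
    """A metric is undefined for the given masks (e.g. both empty)."""

    stage = "metrics"
    exit_code = 6
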