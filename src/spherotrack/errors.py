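"""Exception hierarchy.

``FormatError`` and ``IntegrityError`` concern the input data (malformed
tables, inconsistent observations); ``ParameterError`` concerns caller-supplied
arguments; ``PipelineError`` wraps a failure of a named pipeline stage.
"""


class SpherotrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpherotrackError):
    """The input file cannot be interpreted as a spot-statistics table."""


class IntegrityError(SpherotrackError):
    """The data violate a structural invariant (e.g. duplicate observation)."""


class ParameterError(SpherotrackError):
    """A caller-supplied parameter is out of its valid range."""


class PipelineError(SpherotrackError):
    """A stage of the end-to-end analysis failed; message names the stage."""
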