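"""Exception hierarchy shared across the package.

Validation problems (bad inputs, malformed files, inconsistent records) are
distinguished from estimation failures (an estimator that cannot produce a
defensible number from valid data) and from solver problems, because the
command line maps them to different exit codes.
"""


class GelcellError(Exception):
    """Base class for all package errors."""


class ValidationError(GelcellError):
    """Invalid inputs: bad parameter values, malformed files, inconsistent records."""


class SolverError(GelcellError):
    """The forward solver was configured in a way that produced unusable output."""


class EstimationError(GelcellError):
    """An estimator could not produce a defensible result from otherwise valid data."""
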