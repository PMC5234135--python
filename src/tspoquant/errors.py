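"""Exception hierarchy shared across the pipeline.

Validation problems (bad tables, impossible parameters) raise
:class:`ValidationError` subclasses; numerical failures during model
evaluation or fitting raise :class:`NumericalError` subclasses.  The CLI
maps the former to exit code 2 and the latter to exit code 3.
"""


class TspoQuantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TspoQuantError, ValueError):
    """Invalid user input: malformed tables, out-of-range parameters."""


class ScheduleError(ValidationError):
    """Frame timing is non-monotone, overlapping, or inconsistent."""


class FormatError(ValidationError):
    """A file does not match the expected tabular/image layout."""


class NumericalError(TspoQuantError, RuntimeError):
    """A numerical routine failed (non-convergence, degenerate model)."""


class ModelError(NumericalError):
    """A fitted component model is invalid where it must be evaluated."""
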