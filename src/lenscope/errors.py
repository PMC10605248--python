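"""Exception hierarchy shared across the package.

Exit codes in the CLI distinguish input problems (bad files, bad
parameters) from analysis failures (a computation that cannot proceed on
otherwise valid input).
"""


class LenscopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LenscopeError):
    """A simulation or run configuration violates its invariants.

    The message names the offending field.
    """


class InputError(LenscopeError):
    """Input data (matrix, stack, ROI, gene set) is malformed or inconsistent."""


class MeasurementError(LenscopeError):
    """A measurement is undefined on the given data (e.g. zero background mean)."""


class AnalysisError(LenscopeError):
    """An analysis step cannot proceed (e.g. empty contingency table)."""
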