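"""Exception hierarchy shared across the package.

The command-line interface maps :class:`InputError` to exit code 2 and
:class:`StatisticalError` to exit code 3.
"""


class FmnError(Exception):
    """Base class for all fmnet errors."""


class InputError(FmnError):
    """Malformed, inconsistent or missing input data or configuration."""


class StatisticalError(FmnError):
    """A statistic's preconditions are not met (degenerate or undersized data)."""
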