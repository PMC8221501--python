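"""Exception hierarchy shared by all pipeline stages.

The split mirrors the exit-code contract of the command line interface:
configuration problems (bad parameters, missing columns) exit with 2,
data problems (malformed files, empty cohorts) exit with 1.
"""


class NRNetError(Exception):
    """Base class for all package errors."""


class ParseError(NRNetError):
    """A file could not be parsed; the message names the offending cell."""


class ConfigurationError(NRNetError):
    """Invalid parameter, missing column, or inconsistent request."""


class DataError(NRNetError):
    """Structurally valid input whose content cannot be analysed."""


class InferenceError(NRNetError):
    """Numerical failure during network estimation."""
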