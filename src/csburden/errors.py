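"""Exception hierarchy shared across the pipeline stages.

Each class maps to a distinct process exit code in the command-line
front end so that batch callers can distinguish bad configuration from
bad input data from internal invariant violations.
"""


class CsburdenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(CsburdenError):
    """Invalid option, threshold, resource name or simulation parameter."""

    exit_code = 2


class InputFormatError(CsburdenError):
    """A file or record failed to parse or violated a data invariant."""

    exit_code = 3


class InvariantError(CsburdenError):
    """An internal consistency check failed; indicates a bug."""

    exit_code = 4
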