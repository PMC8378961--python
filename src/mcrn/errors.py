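"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`mcrn.cli`).
"""


class McrnError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(McrnError):
    """An operation was called with out-of-domain parameters."""

    exit_code = 3


class ConfigError(McrnError):
    """Invalid, unknown or conflicting configuration keys/values."""

    exit_code = 3


class IOPathError(McrnError):
    """A path could not be read or written."""

    exit_code = 4


class FormatError(McrnError):
    """Unsupported file format or extension."""

    exit_code = 4


class ShapeError(McrnError):
    """Array shape or channel-count contract violated."""

    exit_code = 5
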