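"""Exception hierarchy.

``InputError`` (and subclasses) map to CLI exit code 2, ``NumericalError``
to exit code 3.
"""


class NetenrichError(Exception):
    """Base class for all package errors."""


class InputError(NetenrichError):
    """Any problem with user-supplied input (files, config, values)."""


class ParseError(InputError):
    """Malformed input file; message carries the offending line number."""


class ConfigError(InputError):
    """Invalid configuration value (unknown channel, preset, missing seed)."""


class ValidationError(InputError):
    """Domain-object invariant violated."""


class GraphConnectivityError(ValidationError):
    """Operation requires a connected graph without isolated nodes."""


class NumericalError(NetenrichError):
    """Numerical failure (singular system, non-convergence)."""
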