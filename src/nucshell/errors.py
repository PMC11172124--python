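"""Exception hierarchy for the nucshell pipeline.

The CLI maps these onto distinct exit codes so batch callers can tell a
bad configuration from degenerate data from an unreadable file.
"""


class NucshellError(Exception):
    """Base class for all package errors."""


class ValidationError(NucshellError):
    """A parameter or input violates a documented precondition."""


class FormatError(NucshellError):
    """An input file is unreadable or has an unsupported layout."""


class DegenerateDataError(NucshellError):
    """The data admit no answer (constant image, zero-distance nucleus, ...)."""


class ConfigurationError(NucshellError):
    """A phantom or run configuration is internally inconsistent."""


class InsufficientReplicatesError(NucshellError):
    """A statistical comparison was requested with fewer than 2 units per group."""


class EmptyResultError(NucshellError):
    """A pipeline stage produced no objects to analyse."""
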