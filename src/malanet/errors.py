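"""Exception hierarchy shared by all malanet modules.

The CLI maps these onto exit codes: usage errors exit 2 (click),
validation/format errors exit 3, anything else exits 4.
"""


class MalanetError(Exception):
    """Base class for all malanet errors."""


class FormatError(MalanetError):
    """A file does not conform to its declared format (missing column, short GMT line...)."""


class ValidationError(MalanetError):
    """Content is well-formed but violates a domain invariant (unknown score entry...)."""


class DomainError(MalanetError):
    """A numeric argument is outside the function's domain."""


class ConfigError(MalanetError):
    """An infeasible or inconsistent configuration."""


class StatError(MalanetError):
    """A statistic is undefined for the given input (e.g. singleton pathway)."""
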