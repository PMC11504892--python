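"""Exception hierarchy.

Three broad families matter to callers (and to the CLI's exit codes):
format errors (bad input files), domain errors (invalid values or
degenerate inputs), and schema errors (mismatched feature tables).
"""


class MirclassError(Exception):
    """Base class for all package errors."""


class FormatError(MirclassError):
    """An input file does not conform to its declared dialect."""


class AlphabetError(FormatError):
    """A sequence contains characters outside the RNA alphabet."""


class DomainError(MirclassError):
    """An operation received values outside its domain."""


class ConfigError(MirclassError):
    """An invalid configuration value."""


class SchemaError(MirclassError):
    """A feature table does not match the schema a model was fitted on."""


class TableAlignmentError(MirclassError):
    """Feature tables being merged do not share the same instance ids."""
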