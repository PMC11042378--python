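"""Exception hierarchy.

``ValidationError`` marks malformed inputs or configuration (CLI exit code 2);
``ComputationError`` marks a well-formed problem the method cannot solve, such
as a degenerate contrast (CLI exit code 3).
"""


class MethRnaError(Exception):
    """Base class for all package errors."""


class ValidationError(MethRnaError):
    """Input file, schema, or configuration is invalid."""


class ComputationError(MethRnaError):
    """A computation cannot proceed on otherwise valid input."""
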