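"""Exception hierarchy.

The command-line layer maps these onto exit codes: configuration problems
exit 2, malformed or inconsistent data exit 3, violated internal
invariants exit 4.
"""


class MultimorbidError(Exception):
    """Base class for all package errors."""


class ConfigError(MultimorbidError):
    """Invalid run configuration (bad threshold, unknown mode, ...)."""


class DataError(MultimorbidError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """Graph or table violates its declared schema."""


class MappingError(DataError):
    """Invalid node-to-category mapping (unknown label, conflict, ...)."""

    def __init__(self, message, conflicts=None):
        super().__init__(message)
        self.conflicts = list(conflicts or [])


class EmptyProfileError(DataError):
    """An intersection with no members cannot yield percentages."""


class InvariantError(MultimorbidError):
    """An internal postcondition failed; indicates a bug, not bad input."""
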