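"""Exception hierarchy for the toolkit.

Every user-facing failure mode has a named error so callers (and the CLI)
can distinguish malformed input from misuse.
"""


class CnidapepError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(CnidapepError):
    """A sequence contains a residue outside the allowed alphabet."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position
        self.char = char
        super().__init__(
            f"record {record_id!r}: illegal residue {char!r} at position {position} "
            "(allowed: 20 standard amino acids plus X)"
        )


class DuplicateIdError(CnidapepError):
    """Two records in one input set share an id."""


class ParseError(CnidapepError):
    """A tabular evidence file has a malformed row."""

    def __init__(self, path, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class UsageError(CnidapepError):
    """The caller asked for something the API does not support."""


class SchemaError(CnidapepError):
    """Two related input files disagree on their shared keys."""


class SpecError(CnidapepError):
    """A synthetic-precursor specification violates its invariants."""
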