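"""Exception hierarchy for the ortex engine."""


class OrtexError(Exception):
    """Base class for all engine errors."""


class FormatError(OrtexError):
    """A file does not conform to the native CSV/JSON dialect."""


class ReferentialError(OrtexError):
    """A record references an undeclared region, injection, or study."""


class DomainError(OrtexError, ValueError):
    """An argument is outside the operation's domain."""


class ConflictError(OrtexError):
    """Raised by strict conflict resolution when conflicts exist.

    Carries the full conflict list so callers can report the core
    statements involved.
    """

    def __init__(self, conflicts):
        self.conflicts = tuple(conflicts)
        super().__init__(
            f"{len(self.conflicts)} unresolved relation conflict(s); "
            "rerun with a non-strict resolution policy to inspect them"
        )


class CellNotFoundError(OrtexError, KeyError):
    """Requested connectivity-matrix cell does not exist."""
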