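"""Exception hierarchy.

Every user-facing failure mode maps onto one of these classes so the CLI
can translate them into stable exit codes (parse/format -> 2, unknown
platform -> 3, consistency -> 4).
"""


class InterlisError(Exception):
    """Base class for all package errors."""


class ParseError(InterlisError):
    """A coordinate or confidence file could not be parsed."""


class FormatError(InterlisError):
    """Input exists but contains no recognizable prediction content."""


class UnknownPlatformError(FormatError):
    """No platform signature matched and no override was given.

    Subclasses :class:`FormatError`: an unrecognized bundle is also
    unrecognizable content; the CLI distinguishes them by exit code.
    """


class AmbiguousPlatformError(InterlisError):
    """More than one platform signature matched the entry names."""


class ConsistencyError(InterlisError):
    """Cross-file disagreement, e.g. PAE dimension vs. residue count."""


class GenerationError(InterlisError):
    """A synthetic fixture specification is geometrically infeasible."""
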