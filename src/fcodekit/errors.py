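"""Exception hierarchy for fcodekit.

Every error raised by the library derives from :class:`FcodeError`, so
callers (and the CLI) can catch one type. Syntax errors additionally
derive from :class:`FcodeSyntaxError` and carry the offending text and,
where known, the character offset.
"""

from __future__ import annotations


class FcodeError(Exception):
    """Base class for all fcodekit errors."""


class FcodeSyntaxError(FcodeError):
    """A code string could not be parsed."""

    def __init__(self, message: str, text: str = "", pos: int | None = None):
        self.text = text
        self.pos = pos
        if pos is not None:
            message = f"{message} (in {text!r} at position {pos})"
        elif text:
            message = f"{message} (in {text!r})"
        super().__init__(message)


class MissingOrigin(FcodeSyntaxError):
    """The code does not start with the origin marker '*'."""


class IllegalSymbol(FcodeSyntaxError):
    """A character outside the relationship legend was found."""


class MissingOrder(FcodeSyntaxError):
    """A sibling or offspring layer lacks its mandatory birth-order number."""


class StrictNumberViolation(FcodeSyntaxError):
    """Strict mode: parent/spouse numbering rule violated."""


class BadOrder(FcodeSyntaxError):
    """A birth-order number is zero, signed, or otherwise malformed."""


class PositionOutOfRange(FcodeError, IndexError):
    """Requested position index outside 0..depth."""


class StaleMatch(FcodeError):
    """A pattern match no longer applies to the code it is used on."""


# --- family / file errors -------------------------------------------------

class FamilyFileError(FcodeError):
    """Base for file-level problems; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TabColumnError(FamilyFileError):
    """A data line does not have exactly two tab-separated columns."""


class InvalidFcode(FamilyFileError):
    """A code column failed to parse."""


class DuplicateFcode(FamilyFileError):
    """Two records resolve to the same canonical code."""


class ForeignOrigin(FamilyFileError):
    """A code column does not start with '*'."""


class HeaderMismatch(FamilyFileError):
    """A TSV header contains unknown or misordered columns."""


class InconsistentFamily(FcodeError):
    """Records force contradictory sexes or parentage on one person."""


class UnknownPerson(FcodeError):
    """A code does not resolve to any person in the family."""


class Disconnected(FcodeError):
    """A person is unreachable from the requested origin."""


class BadRegex(FcodeError):
    """A search pattern is not a valid regular expression."""


class Infeasible(FcodeError):
    """The random generator could not satisfy the requested constraints."""
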