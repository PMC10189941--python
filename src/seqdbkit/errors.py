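"""Exception hierarchy.

``SeqDbError`` is the root for data-level problems (CLI exit code 2);
``UsageError`` marks bad invocations (CLI exit code 1).
"""


class SeqDbError(Exception):
    """Base class for all data-level errors raised by this package."""


class UsageError(SeqDbError):
    """The caller asked for something contradictory or malformed."""


# --- sequences and headers ---------------------------------------------------

class EmptySequence(SeqDbError):
    pass


class IllegalCharacter(SeqDbError):
    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(f"illegal character {char!r} at position {position}")


class MalformedHeader(SeqDbError):
    pass


# --- text formats ------------------------------------------------------------

class NotFasta(SeqDbError):
    pass


class EmptyRecord(SeqDbError):
    pass


class MalformedTag(SeqDbError):
    pass


class NotPeff(SeqDbError):
    pass


class FileUnreadable(SeqDbError):
    pass


# --- SQPD --------------------------------------------------------------------

class PathExists(SeqDbError):
    pass


class InvalidMeta(SeqDbError):
    pass


class DuplicateAccession(SeqDbError):
    pass


class AccessionNotFound(SeqDbError):
    pass


class NotSqpd(SeqDbError):
    pass


class MalformedFeatureCell(SeqDbError):
    pass


# --- SET ---------------------------------------------------------------------

class NotSet(SeqDbError):
    pass


class DuplicateEntryInSet(SeqDbError):
    pass


class MissingAccession(SeqDbError):
    pass


# --- retrieval ---------------------------------------------------------------

class TransportError(SeqDbError):
    pass


class EmptyResult(SeqDbError):
    """A well-formed response that contains no hits (not a failure)."""


class VersionExists(SeqDbError):
    pass


class UnknownDb(SeqDbError):
    pass


# --- generation --------------------------------------------------------------

class TagCollision(SeqDbError):
    pass


class LengthNotMultipleOfThree(SeqDbError):
    pass


class FeatureOutOfRange(SeqDbError):
    pass


# --- filtering / analysis ----------------------------------------------------

class UnknownField(SeqDbError):
    pass


class MissingColumn(SeqDbError):
    pass


class NonNumericColumn(SeqDbError):
    pass


class BadPattern(SeqDbError):
    pass


class SiteOutOfRange(SeqDbError):
    pass
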