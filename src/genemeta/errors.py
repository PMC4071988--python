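"""Exception hierarchy for genemeta."""


class GenemetaError(Exception):
    """Base class for all genemeta errors."""


class SchemaError(GenemetaError):
    """Input table does not have the required columns."""


class ValidationError(GenemetaError):
    """A value violates a data-model invariant."""


class DegenerateTableError(GenemetaError):
    """A 2x2 table has a zero cell and no continuity correction is active."""


class UndefinedEffectError(GenemetaError):
    """The odds ratio is undefined even after correction (an empty margin)."""


class InsufficientStudiesError(GenemetaError):
    """Too few studies for the requested synthesis or diagnostic."""


class UnknownFixtureError(GenemetaError, KeyError):
    """Requested bundled dataset does not exist."""
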