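"""Exception hierarchy shared by all stages."""


class LncArrayError(Exception):
    """Base class for all package errors."""


class SchemaError(LncArrayError):
    """An input table is missing a required column or header."""


class IntegrityError(LncArrayError):
    """Cross-references between inputs are inconsistent (duplicate ids,
    records pointing at entries that do not exist, ...)."""


class ValidationError(LncArrayError):
    """A value violates its documented domain (negative intensity,
    p-value outside [0, 1], start > end, ...)."""
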