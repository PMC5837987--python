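"""Exception hierarchy shared by all taxafunc modules."""


class TaxafuncError(Exception):
    """Base class for all errors raised by taxafunc."""


class InputFormatError(TaxafuncError):
    """A user-provided file or argument violates the input contract.

    Raised for malformed tables, duplicate identifiers, negative
    abundances, inconsistent hierarchies, and similar validation
    failures.  The CLI maps this class to exit code 2.
    """


class InvariantError(TaxafuncError):
    """An internal consistency check failed.

    Indicates a bug or a numerically impossible state rather than bad
    input.  The CLI maps this class to exit code 3.
    """
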