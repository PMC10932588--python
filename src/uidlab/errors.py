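"""Exception hierarchy shared across the package."""


class UidlabError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(UidlabError, ValueError):
    """A precondition on an argument was violated (empty corpus, bad counts, ...)."""


class FormatError(UidlabError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(UidlabError, ValueError):
    """Parsed data violates a semantic invariant (negative surprisal, role mismatch, ...)."""


class InfiniteSurprisalError(UidlabError, ArithmeticError):
    """An MLE model assigned probability zero to an observed event.

    Carries a diagnostic naming the token and conditioning context so the
    offending event can be located in the scored sentence.
    """

    def __init__(self, token: str, context: tuple[str, ...]):
        self.token = token
        self.context = context
        super().__init__(
            f"zero probability under MLE for token {token!r} in context "
            f"{' '.join(context)!r}; use add_k smoothing for finite surprisal"
        )


class DegenerateTestError(UidlabError, ValueError):
    """A statistical test is undefined for the given inputs (e.g. zero-variance t)."""
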