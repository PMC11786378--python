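"""Shared exception types.

``ExcludedInputError`` marks inputs that are *valid* but outside an
operation's analytical scope (e.g. single-isoform genes for entropy,
genes in fewer than two complexes for partner counting).  Callers
iterating over many genes catch it and record the exclusion reason
rather than aborting.
"""


class ExcludedInputError(ValueError):
    """Input is well-formed but excluded from this analysis by design."""

    def __init__(self, message: str, reason: str = "excluded"):
        super().__init__(message)
        self.reason = reason


class SingleIsoformGeneError(ExcludedInputError):
    """Gene annotated with a single isoform; entropy/divergence undefined."""

    def __init__(self, gene: str):
        super().__init__(
            f"gene {gene!r} is annotated as a single-isoform gene",
            reason="single_isoform",
        )


class UnexpressedGeneError(ExcludedInputError):
    """Gene has zero expression in every sample considered."""

    def __init__(self, gene: str):
        super().__init__(
            f"gene {gene!r} is unexpressed in all samples", reason="unexpressed"
        )
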