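"""Exception types shared across the pipeline."""


class ContractError(ValueError):
    """A precondition or invariant of an operation was violated."""


class EdgeListParseError(ValueError):
    """An input edge-list file could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EntityLookupError(KeyError):
    """A named entity is unknown to the feature/matrix object queried."""

    def __init__(self, entity: str, context: str = ""):
        msg = f"unknown entity {entity!r}" + (f" in {context}" if context else "")
        super().__init__(msg)
        self.entity = entity

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]
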