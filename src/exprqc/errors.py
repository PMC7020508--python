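"""Exception hierarchy shared across the package.

All anticipated user-input problems raise :class:`ExprQCError` subclasses so
the command-line layer can distinguish validation failures (exit code 1)
from genuine runtime faults (exit code 2).
"""


class ExprQCError(Exception):
    """Base class for all anticipated errors raised by exprqc."""


class SchemaError(ExprQCError):
    """An input file is missing a required column or has the wrong layout."""


class ValidationError(ExprQCError):
    """An input file parses but violates a content invariant."""


class StageError(ExprQCError):
    """A pipeline stage failed; carries the stage name for the run log."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
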