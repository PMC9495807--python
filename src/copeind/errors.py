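"""Exception hierarchy.

Problems with input data or configuration raise :class:`ValidationError`
(the CLI maps these to exit code 2); everything else surfaces as an
ordinary runtime error (exit code 1).
"""


class ValidationError(ValueError):
    """Input data or configuration violates a documented contract."""


class SchemaError(ValidationError):
    """A table is structurally malformed (duplicate ids, bad vocabulary)."""


class DesignError(ValidationError):
    """A synthetic-community design is internally infeasible."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
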