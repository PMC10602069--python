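"""Exception hierarchy shared across the package."""


class BfhdeError(Exception):
    """Base class for all package-specific errors."""


class SingularDesignError(BfhdeError):
    """Design matrix is rank deficient; the normal equations have no unique solution."""


class InsufficientDataError(BfhdeError):
    """Too few observations to estimate the requested quantities."""


class InvalidPriorError(BfhdeError):
    """Prior specification violates positivity or shape requirements."""


class InvalidInputError(BfhdeError):
    """An argument is outside its documented domain."""


class EmptyResultError(BfhdeError):
    """A filtering or intersection step removed everything."""


class PipelineError(BfhdeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
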