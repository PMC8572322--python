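"""Exception hierarchy shared across the package."""


class RaschmonError(Exception):
    """Base class for all package errors."""


class ConfigError(RaschmonError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DomainError(RaschmonError, ValueError):
    """Numeric argument outside its mathematical domain."""


class InestimableItemError(RaschmonError):
    """An item was answered correctly by everyone or no one among the
    respondents with interior raw scores, so its conditional MLE diverges."""

    def __init__(self, item_codes, context=""):
        self.item_codes = list(item_codes)
        suffix = f" ({context})" if context else ""
        super().__init__(
            f"inestimable item(s) {', '.join(map(str, self.item_codes))}: "
            f"answered by all or by none of the scoreable respondents{suffix}"
        )


class ConvergenceError(RaschmonError):
    """Newton iteration failed to reach the gradient tolerance."""

    def __init__(self, grad_norm, n_iter):
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        super().__init__(
            f"CML fit did not converge after {n_iter} iterations "
            f"(last gradient max-norm {grad_norm:.3e})"
        )


class DegenerateSplitError(RaschmonError):
    """A sample split produced an empty subgroup."""


class ResponseFormatError(RaschmonError, ValueError):
    """Base for response-file validation failures."""


class DuplicateRespondentError(ResponseFormatError):
    """Duplicate respondent identifiers in a response table."""


class NonBinaryValueError(ResponseFormatError):
    """A response cell holds something other than 0 or 1."""


class MissingValueError(ResponseFormatError):
    """A response cell is empty; complete data is a hard requirement."""


class UnmatchedWorkerError(RaschmonError, KeyError):
    """Workers could not be joined to a centre burden record."""

    def __init__(self, ids, what="centre record"):
        self.ids = list(ids)
        super().__init__(f"no {what} for worker(s): {', '.join(map(str, self.ids))}")


class PipelineStageError(RaschmonError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage, error):
        self.stage = stage
        self.error = error
        super().__init__(f"pipeline stage '{stage}' failed: {error}")
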