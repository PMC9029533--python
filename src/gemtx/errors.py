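"""Exception hierarchy shared across the package."""


class GemtxError(Exception):
    """Base class for all package errors."""


class ModelFormatError(GemtxError):
    """A model file could not be parsed in its declared format."""


class SchemaError(GemtxError):
    """An input table is missing required columns or sheets."""


class ValidationError(GemtxError):
    """Parsed data violates a domain invariant."""


class GprParseError(GemtxError):
    """A gene-protein-reaction rule string is malformed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class OptimizationError(GemtxError):
    """An LP could not be solved (infeasible/unbounded/solver failure)."""


class InfeasibleContextError(OptimizationError):
    """A context-specific model is infeasible; carries the active constraints."""

    def __init__(self, message: str, active_constraints=None):
        self.active_constraints = list(active_constraints or [])
        if self.active_constraints:
            detail = "; ".join(str(c) for c in self.active_constraints[:20])
            message = f"{message}. Active constraints: {detail}"
        super().__init__(message)


class UsageError(GemtxError):
    """Invalid combination of run options (CLI-level error, exit code 2)."""
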