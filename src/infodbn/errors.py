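"""Exception hierarchy shared across the pipeline."""


class InfoDBNError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(InfoDBNError, ValueError):
    """An argument is outside its admissible range or combination."""


class InfeasibleGraphError(ParameterError):
    """Requested arc counts cannot be placed in the available graph slots."""


class UnstableModelError(InfoDBNError):
    """A VAR(1)-style ground truth is not stationary (spectral radius >= 1)."""


class PanelFormatError(InfoDBNError, ValueError):
    """A panel violates its structural invariants (nesting, contiguity, ...)."""


class EmptyResultError(InfoDBNError):
    """An operation removed every row/column/condition it was given."""


class DegenerateDesignError(InfoDBNError):
    """A local regression design matrix is singular (collinear parents)."""

    def __init__(self, node: str, detail: str = ""):
        self.node = node
        msg = f"singular design for node {node!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class UnimputableSeriesError(InfoDBNError):
    """A series has too few observed values to impute."""
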