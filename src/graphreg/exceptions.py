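"""Exception hierarchy for graphreg."""


class GraphRegError(Exception):
    """Base class for all graphreg errors."""


class InputError(GraphRegError):
    """Malformed or inconsistent user input (shapes, ids, ranges)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but numerically degenerate
    (e.g. a zero-variance column that cannot be standardized)."""


class NumericalFailureError(GraphRegError):
    """A variational update produced a non-finite value.

    Carries the coefficient index at which the failure occurred, when known.
    """

    def __init__(self, message: str, coefficient: int | None = None):
        super().__init__(message)
        self.coefficient = coefficient
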