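"""Exception hierarchy for coxmix."""


class CoxmixError(Exception):
    """Base class for all coxmix errors."""


class FormatError(CoxmixError):
    """A genomic input file violates its format contract.

    The message always names the file and, where applicable, the
    1-based line number of the first offending line.
    """


class ConvergenceError(CoxmixError):
    """Newton optimisation failed to reach the gradient tolerance."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm
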