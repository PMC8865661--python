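"""Exception types shared across the package."""


class SynFilterError(RuntimeError):
    """Base class for runtime failures of the filtering machinery."""


class DivergenceError(SynFilterError):
    """Raised when an exponent overflows, signalling a runaway membrane
    potential or a divergent belief."""


class VarianceCollapseError(SynFilterError):
    """Raised when a posterior variance becomes non-positive.

    The covariance ODE is stiff when the expected rate is large; the standard
    remedy is a smaller integration step.
    """


class DegenerateEnsembleError(SynFilterError):
    """Raised when every particle has zero likelihood (all log-weights -inf)."""
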