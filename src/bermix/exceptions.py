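"""Exception hierarchy used across the package."""


class BermixError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BermixError, ValueError):
    """Raised when user-supplied data or parameters violate a contract."""


class DegenerateSampleError(BermixError):
    """Raised when a sample has probability zero under every latent cluster.

    Carries the offending sample identifier so the user can locate it.
    """

    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        super().__init__(
            f"sample {sample_id!r} has zero probability under every cluster; "
            "use a positive Dirichlet offset gamma to smooth compositions"
        )


class NumericalError(BermixError):
    """Raised when the optimizer produces a non-finite objective."""

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)
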