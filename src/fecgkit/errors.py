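"""Exception hierarchy shared across the toolkit."""


class FecgkitError(Exception):
    """Base class for all fecgkit errors."""


class FormatError(FecgkitError):
    """Malformed on-disk data (missing metadata, ragged rows, NaN cells...)."""


class ParameterError(FecgkitError, ValueError):
    """Invalid user-supplied parameter."""


class DegenerateInputError(FecgkitError):
    """Input that is structurally unusable (zero variance, rank deficient...)."""


class RoleAssignmentError(FecgkitError):
    """No ICA component matches the expected maternal rate band."""


class NumericalInstabilityError(FecgkitError):
    """Non-finite values appeared during an adaptive recursion."""

    def __init__(self, message: str, sample_index: int | None = None):
        super().__init__(message)
        self.sample_index = sample_index
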