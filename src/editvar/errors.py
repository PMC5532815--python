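"""Exception types shared across the package."""


class EditvarError(Exception):
    """Base class for package errors."""


class ParameterError(EditvarError, ValueError):
    """An argument or configuration value is outside its admissible range."""


class DataError(EditvarError, ValueError):
    """Input data violate a precondition (e.g. monomorphic haplotypes)."""


class CoordinateError(EditvarError, ValueError):
    """A genomic coordinate falls outside the reference being queried."""


class UntestableError(EditvarError):
    """The requested test is undefined for these data (no contrast, too few
    replicates, zero coverage everywhere)."""


class NonConvergenceError(EditvarError):
    """An optimizer failed to converge; diagnostics attached when available."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
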