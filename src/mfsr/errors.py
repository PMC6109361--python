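"""Exception hierarchy shared across the package.

The CLI maps these onto distinct process exit codes (see :mod:`mfsr.cli`).
"""


class MFSRError(Exception):
    """Base class for all package errors."""


class SpecError(MFSRError, ValueError):
    """Invalid or inconsistent declarative specification."""


class DataError(MFSRError, ValueError):
    """Input data violates a precondition (shape, mask, range...)."""


class SizingError(DataError):
    """Array too small for the requested operation."""


class TrainingDivergence(MFSRError, RuntimeError):
    """Loss became non-finite during optimisation."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"non-finite loss at iteration {iteration}")
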