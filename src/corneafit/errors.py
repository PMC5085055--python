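"""Package-wide exception types."""

from __future__ import annotations


class ConfigurationError(ValueError):
    """Invalid geometry, material or run configuration."""


class NonConvergenceError(RuntimeError):
    """The nonlinear solver failed to reach equilibrium.

    Attributes
    ----------
    last_converged_fraction:
        Fraction of the requested load that was equilibrated before failure.
    frame_index:
        Index of the failing frame when raised from a time sweep, else None.
    """

    def __init__(
        self,
        message: str,
        last_converged_fraction: float = 0.0,
        frame_index: int | None = None,
    ) -> None:
        super().__init__(message)
        self.last_converged_fraction = last_converged_fraction
        self.frame_index = frame_index


class CapabilityError(RuntimeError):
    """An operation needs record contents that a reduced record does not carry."""


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
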