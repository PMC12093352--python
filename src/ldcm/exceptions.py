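"""Structured errors raised by the modelling pipeline."""


class LdcmError(Exception):
    """Base class for all package errors."""


class LayoutError(LdcmError):
    """Parameter vector does not match the layout implied by a model variant."""


class FixedPointError(LdcmError):
    """Newton iteration for the noise-free equilibrium failed to converge."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class StabilityError(LdcmError):
    """The linearised system is not stable; no stationary spectrum exists."""


class DesignError(LdcmError):
    """A condition design or group design is inconsistent with its inputs."""


class DataError(LdcmError):
    """Input data violate a precondition (shape, finiteness, Hermitian symmetry)."""
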