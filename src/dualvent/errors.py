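"""Exception types shared across the package."""


class DualVentError(Exception):
    """Base class for all package errors."""


class PhaseError(DualVentError):
    """A waveform was evaluated outside its breathing-cycle phase."""


class ConfigError(DualVentError):
    """Invalid or inconsistent configuration input."""


class SolverError(DualVentError):
    """The network solver or ODE integrator failed."""

    def __init__(self, message, t_last=None, branch=None):
        super().__init__(message)
        self.t_last = t_last
        self.branch = branch


class TuningError(DualVentError):
    """A valve-tuning target could not be reached."""

    def __init__(self, message, max_achievable=None):
        super().__init__(message)
        self.max_achievable = max_achievable


class DegenerateModelError(DualVentError):
    """The linear model is degenerate (e.g. repeated eigenvalues with a
    singular eigenvector matrix)."""


class FitError(DualVentError):
    """A nonlinear least-squares fit failed or produced unphysical values."""
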