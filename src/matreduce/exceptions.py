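"""Exception types shared across the package."""


class MatreduceError(Exception):
    """Base class for package-specific errors."""


class SimulationDivergedError(MatreduceError):
    """The forward-Euler trajectory produced a non-finite state."""

    def __init__(self, step: int, time_ms: float):
        self.step = step
        self.time_ms = time_ms
        super().__init__(
            f"non-finite state at step {step} (t = {time_ms:.3f} ms); "
            "reduce dt or check the stimulus"
        )


class NotSubthresholdError(MatreduceError):
    """A spike occurred where a subthreshold (non-spiking) regime was required."""


class ConvergenceError(MatreduceError):
    """An iterative procedure failed to converge."""


class BracketError(MatreduceError):
    """A bisection/bracketing search could not bracket its target."""


class ContaminationError(MatreduceError):
    """A second spike intruded into a single-spike analysis window."""


class FitFailureError(MatreduceError):
    """A least-squares kernel fit returned unphysical parameters."""


class DegenerateRateError(MatreduceError):
    """The coincidence-factor normalization 1 - 2*nu*Delta is non-positive."""


class SingularSensitivityError(MatreduceError):
    """The threshold slope vanishes; noise sensitivity is undefined."""


class UnfittableError(MatreduceError):
    """The training data cannot constrain the reduced model (e.g. no spikes)."""


class ParseError(MatreduceError):
    """A text artifact could not be parsed."""

    def __init__(self, path, line: int, message: str):
        self.path = path
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class ConfigError(MatreduceError):
    """A run configuration is invalid or incomplete."""
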