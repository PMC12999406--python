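"""Exception hierarchy for the pipeline."""


class CPRStressError(Exception):
    """Base class for all package errors."""


class ValidationError(CPRStressError, ValueError):
    """Invalid parameter or out-of-domain input."""


class UnusableSignalError(CPRStressError):
    """A trace or beat series is too degraded to analyze."""


class InfeasibleRandomizationError(CPRStressError):
    """No dyad assignment satisfies the pairing constraint."""

    def __init__(self, message, blocking=()):
        super().__init__(message)
        self.blocking = list(blocking)


class PipelineError(CPRStressError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage, message, offending=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.offending = offending
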