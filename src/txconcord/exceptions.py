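"""Exception hierarchy shared across the package."""


class TxConcordError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TxConcordError, ValueError):
    """A file violates the expected on-disk format."""


class ValidationError(TxConcordError, ValueError):
    """An in-memory object or argument violates an invariant."""


class OrientationError(TxConcordError, ValueError):
    """Contrast orientation stamps disagree and no explicit flip was requested."""


class ConvergenceError(TxConcordError, RuntimeError):
    """An iterative fit failed to converge."""


class PipelineError(TxConcordError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
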