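"""Exception hierarchy. Every error names the pipeline stage it came from."""


class FiberVitalsError(Exception):
    """Base class; carries a stage label and a short reason code."""

    stage = "fibervitals"
    reason = "error"

    def __init__(self, message: str = ""):
        super().__init__(f"[{self.stage}:{self.reason}] {message}" if message else
                         f"[{self.stage}:{self.reason}]")


class InvalidParamsError(FiberVitalsError):
    stage = "synth"
    reason = "invalid-params"


class AliasingError(FiberVitalsError):
    stage = "synth"
    reason = "aliasing"


class ArtifactRangeError(FiberVitalsError):
    stage = "synth"
    reason = "artifact-out-of-bounds"


class InsufficientDataError(FiberVitalsError):
    stage = "synth"
    reason = "insufficient-data"


class DegenerateChannelError(FiberVitalsError):
    stage = "demod"
    reason = "degenerate-channel"


class InsufficientLengthError(FiberVitalsError):
    stage = "spectral"
    reason = "insufficient-length"


class EmptyFrameError(FiberVitalsError):
    stage = "spectral"
    reason = "empty-frame"


class FormatError(FiberVitalsError):
    stage = "io"
    reason = "format"
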