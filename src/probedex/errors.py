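"""Exception hierarchy shared across the package."""


class ProbedexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ProbedexError, ValueError):
    """Invalid configuration (bad alpha, impossible probe tiling, ...)."""


class InputError(ProbedexError, ValueError):
    """Invalid input data (non-positive intensity, unknown transcript, ...)."""


class ParseError(InputError):
    """Malformed input file; message carries file coordinates."""


class PipelineError(ProbedexError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
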