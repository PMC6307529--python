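"""Exception hierarchy shared across the toolkit."""


class PtebioError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PtebioError):
    """A file parsed, but its content violates the expected dialect."""


class DataIntegrityError(PtebioError):
    """Loaded data contain values that make downstream analysis invalid."""


class ArgumentError(PtebioError, ValueError):
    """An operation was called with arguments outside its contract."""


class StageError(PtebioError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
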