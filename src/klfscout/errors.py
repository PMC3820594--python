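"""Exception hierarchy shared by all pipeline stages."""


class KlfScoutError(Exception):
    """Base class for all klfscout errors."""


class MalformedInputError(KlfScoutError):
    """Input violates a structural precondition (overlaps, duplicates, bad format)."""


class NotApplicableError(KlfScoutError):
    """An operation was requested on data it is not defined for."""


class ParseError(MalformedInputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str = "", line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class StageError(KlfScoutError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
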