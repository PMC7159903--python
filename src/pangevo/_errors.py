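"""Exception hierarchy shared across the pipeline."""


class PangevoError(Exception):
    """Base class for all package errors."""


class FormatError(PangevoError):
    """A table or sequence file does not match the documented dialect."""


class IntegrityError(PangevoError):
    """Cross-references between tables are inconsistent."""


class ConfigError(PangevoError):
    """A configuration value is out of its valid range."""


class SizingError(PangevoError):
    """A simulation request cannot be satisfied with the given budget."""


class DomainError(PangevoError):
    """A statistic was requested outside its mathematical domain."""


class StageError(PangevoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
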