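"""Exception types shared across the package."""


class TracheoguideError(Exception):
    """Base class for package-specific errors."""


class ConfigError(TracheoguideError):
    """A configuration file or value is invalid or missing."""


class FrameMismatchError(TracheoguideError, ValueError):
    """Poses expressed in different frames with no registration transform."""


class SchemaError(TracheoguideError, ValueError):
    """A tracker-log file violates the documented dialect schema."""


class OrderingError(TracheoguideError, ValueError):
    """Timestamps in a tracker log are not monotone (strict mode)."""


class StageError(TracheoguideError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
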