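"""Exception hierarchy shared across the package."""


class MirsigError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MirsigError):
    """A required top-table column could not be resolved."""


class AmbiguousColumnError(SchemaError):
    """Two or more source columns map to the same canonical field."""


class EmptyInputError(MirsigError):
    """An input file or table contained no usable rows."""


class GMTParseError(MirsigError):
    """A GMT line did not have at least name, description and one member."""


class UniverseError(MirsigError):
    """Background universe construction or library restriction failed."""


class ConfigError(MirsigError):
    """A run configuration or synthetic-data spec violates an invariant."""


class PipelineStageError(MirsigError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
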