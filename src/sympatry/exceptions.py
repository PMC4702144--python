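"""Exception hierarchy for the sympatry pipeline."""


class SympatryError(Exception):
    """Base class for all package errors."""


class ConfigError(SympatryError):
    """Invalid simulation or run configuration."""


class InputError(SympatryError):
    """Malformed or out-of-contract input data."""


class SchemaError(InputError):
    """A required column is missing from a tabular input."""

    def __init__(self, column: str, table: str = "input"):
        self.column = column
        self.table = table
        super().__init__(f"{table} is missing required column {column!r}")


class DegenerateDiveError(InputError):
    """A dive segment is too short to extract shape metrics from."""


class UndefinedResultError(SympatryError):
    """The requested quantity is undefined for the given data
    (e.g. a foraging-depth mode with no foraging dives)."""


class PipelineError(SympatryError):
    """A pipeline stage failed; the stage name is included in the message."""
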