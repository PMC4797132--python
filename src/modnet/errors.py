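"""Exception hierarchy shared across the package."""


class ModnetError(Exception):
    """Base class for all package-specific errors."""


class IntegrityError(ModnetError):
    """A referenced node/edge/group does not exist in the network."""


class ConflictError(ModnetError):
    """An operation would violate a uniqueness or disjointness invariant."""


class ArityError(ModnetError):
    """A hyperedge was given fewer than two participants."""


class NodeLookupError(ModnetError, KeyError):
    """Lookup of an unknown node id."""


class FormatError(ModnetError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConfigurationError(ModnetError):
    """A required configuration item (e.g. a score column) is missing or invalid."""


class StageError(ModnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
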