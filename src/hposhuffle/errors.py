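"""Exception hierarchy shared across the pipeline."""


class HpoShuffleError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HpoShuffleError):
    """A file does not follow the expected dialect (names the offending line/row)."""


class CycleError(HpoShuffleError):
    """The is_a links of an ontology contain a directed cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"cyclic is_a chain: {' -> '.join(self.cycle)}")


class ValidationError(HpoShuffleError, ValueError):
    """An argument or data structure violates a documented invariant."""


class StageError(HpoShuffleError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
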