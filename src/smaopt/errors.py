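"""Exception hierarchy for the smaopt workflow.

All contract-style failures derive from :class:`ValueError` so callers that
only care about "bad input" can catch one base class.
"""


class SmaoptError(ValueError):
    """Base class for all smaopt errors."""


class ParameterizationError(SmaoptError):
    """An ill-formed grid, Sobol, or ratio specification."""


class ContractError(SmaoptError):
    """A violated operation precondition (dimension mismatch, empty input, ...)."""


class TrainingError(SmaoptError):
    """A surrogate could not be fitted (e.g. too few samples for the basis)."""


class FormatError(SmaoptError):
    """A malformed dataset file (wrong columns, unparsable row)."""


class ConfigError(SmaoptError):
    """An invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending artifact."""

    def __init__(self, stage: str, message: str, artifact: str | None = None):
        self.stage = stage
        self.artifact = artifact
        detail = f"stage '{stage}': {message}"
        if artifact:
            detail += f" (artifact: {artifact})"
        super().__init__(detail)
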