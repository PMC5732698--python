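"""Exception hierarchy shared across the pipeline."""


class PhosphonetError(Exception):
    """Base class for all package errors."""


class SchemaError(PhosphonetError):
    """An input table is missing a required column or has a malformed layout."""


class ValidationError(PhosphonetError):
    """Input values violate a documented invariant (bad residue, bad range...)."""


class ParameterError(PhosphonetError):
    """A parameter is outside its valid range."""


class StageError(PhosphonetError):
    """A pipeline stage failed; carries the stage name for machine handling."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
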