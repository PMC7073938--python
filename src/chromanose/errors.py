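"""Exception hierarchy for chromanose."""


class ChromanoseError(Exception):
    """Base class for all chromanose errors."""


class DomainError(ChromanoseError, ValueError):
    """An input violates a documented precondition (range, arity, shape)."""


class LayoutError(ChromanoseError, ValueError):
    """A spot-grid geometry does not fit, or discs overlap."""


class FormatError(ChromanoseError, ValueError):
    """A serialized table or model does not match the documented schema."""


class SplitError(ChromanoseError, ValueError):
    """A stratified split cannot be realized (empty or too-small stratum)."""


class TrainingError(ChromanoseError, RuntimeError):
    """Network training diverged (non-finite loss)."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
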