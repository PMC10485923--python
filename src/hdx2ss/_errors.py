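"""Exception hierarchy shared across the package."""


class HdxError(Exception):
    """Base class for all hdx2ss errors."""


class FormatError(HdxError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(HdxError):
    """Input data violates a documented invariant."""


class DegenerateControlError(ValidationError):
    """BEX control does not exceed FEX control for a peptide, so the
    two-point RFU normalization is undefined."""


class DegenerateTargetError(ValidationError):
    """Training targets contain a single class."""


class ConvergenceError(HdxError):
    """Optimizer failed to converge in every replicate; carries the loss
    trajectories for diagnosis."""

    def __init__(self, message: str, loss_trajectories=None):
        super().__init__(message)
        self.loss_trajectories = loss_trajectories or []
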