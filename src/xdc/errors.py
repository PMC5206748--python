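"""Exception hierarchy for the xdc pipeline."""


class XdcError(Exception):
    """Base class for all xdc errors."""


class FormatError(XdcError):
    """A structure file could not be parsed."""


class EmptyStructureError(XdcError):
    """A parsed file contained no atoms / no model."""


class EmptySelectionError(XdcError):
    """A selection resolved to zero atoms."""


class IllPosedError(XdcError):
    """A geometric problem is degenerate (too few points, collinear, ...)."""


class PairingError(XdcError):
    """Residue pairing between two structures failed."""


class FitConvergenceError(XdcError):
    """A nonlinear fit did not converge; carries the final residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm
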