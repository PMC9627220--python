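"""Exception types shared across the package."""


class SpecfxError(ValueError):
    """Base class for domain errors raised by specfx."""


class PeakTableParseError(SpecfxError):
    """A delimited peak table could not be parsed; carries file and line."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [file: {path}"
            loc += f", line {line}]" if line is not None else "]"
        super().__init__(message + loc)


class AmbiguousMatchError(SpecfxError):
    """Two peaks from one batch fall inside the retention-time tolerance."""


class FitError(SpecfxError):
    """A model fit failed to converge; carries the residual norm when known."""

    def __init__(self, message: str, residual_norm=None):
        self.residual_norm = residual_norm
        if residual_norm is not None:
            message += f" (residual norm {residual_norm:.6g})"
        super().__init__(message)
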