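"""Exception hierarchy shared across the package."""


class SaxskitError(Exception):
    """Base class for all package errors."""


class ProfileFormatError(SaxskitError):
    """A profile file could not be parsed; the message names the first bad line."""


class InsufficientDataError(SaxskitError):
    """Fewer usable data points than an operation requires."""


class GridMismatchError(SaxskitError):
    """Two profiles do not share a q grid and interpolation was not requested."""


class EmptyWindowError(SaxskitError):
    """A q-window restriction produced an empty profile."""


class NoPeakError(SaxskitError):
    """No interior Kratky maximum exists on the evaluated range."""
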