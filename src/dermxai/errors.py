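"""Exception hierarchy shared across the package."""


class DermxaiError(Exception):
    """Base class for package errors."""


class InputError(DermxaiError):
    """A caller violated an operation's preconditions (shape, range, name)."""


class NumericError(DermxaiError):
    """Non-finite values were encountered where finite ones are required."""


class EstimationError(DermxaiError):
    """A model fit could not be carried out (degenerate design, etc.)."""
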