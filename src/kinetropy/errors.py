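"""Exception types raised by kinetropy readers, validators and fitters."""


class KinetropyError(Exception):
    """Base class for all package errors."""


class FormatError(KinetropyError):
    """A tabular input file does not match the expected dialect."""


class DuplicateRecordError(FormatError):
    """Two rows claim the same (state, methyl) or equivalent key."""


class ValidationError(KinetropyError):
    """A value violates a physical or structural invariant (negative delay,
    population outside its range, non-PSD covariance, ...)."""


class FitError(KinetropyError):
    """A nonlinear fit failed to converge or is structurally unidentifiable."""
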