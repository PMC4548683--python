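"""Exception hierarchy for mnasim."""


class MnasimError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MnasimError, ValueError):
    """A physical specification (column, site, schedule) violates its invariants."""


class ValidationError(MnasimError, ValueError):
    """Input data failed schema or consistency validation."""


class NumericsError(MnasimError, RuntimeError):
    """A numerical solve became unstable or produced non-finite values."""


class FitError(MnasimError, RuntimeError):
    """A calibration failed to converge or the data carry no signal."""
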