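"""Exception and warning types shared across the package."""


class BloodPoolDosimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BloodPoolDosimError, ValueError):
    """An input object violates one of its invariants."""


class UndefinedRatioError(BloodPoolDosimError, ZeroDivisionError):
    """A fraction was requested over an all-zero denominator."""


class FitError(BloodPoolDosimError, ValueError):
    """A model fit is degenerate or non-identifiable for the given data."""


class SchemaMismatchError(BloodPoolDosimError, KeyError):
    """Source/target regions of two dosimetry objects do not line up."""


class ExtrapolationWarning(UserWarning):
    """A model is being evaluated well outside its fitted range."""
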