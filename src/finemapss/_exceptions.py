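"""Exception hierarchy separating bad inputs from numerical failures."""


class FinemapError(Exception):
    """Base class for all package errors."""


class InputError(FinemapError):
    """Malformed or missing inputs (wrong dimensions, absent columns, bad flags)."""


class ValidationError(InputError):
    """Inputs that are structurally present but fail a domain invariant
    (e.g. a non-positive standard error, a zero-variance genotype column)."""


class NumericalError(FinemapError):
    """A computation produced non-finite or otherwise unusable values."""
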