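"""Exception hierarchy for hemomir.

All package errors derive from :class:`HemomirError` so callers can catch
one base class; specific subclasses mark the contract that was violated.
"""


class HemomirError(Exception):
    """Base class for all hemomir errors."""


class FormatError(HemomirError):
    """A file does not conform to the expected dialect (bad header,
    duplicate assay names, unparsable cells)."""


class ValidationError(HemomirError):
    """Parsed data violate a domain invariant (Cq out of range,
    negative optical density, non-monotone wavelength grid)."""


class ConfigurationError(HemomirError):
    """Parameters are internally inconsistent (threshold larger than the
    sample count, label proportions not summing to one, missing baseline)."""


class DesignError(HemomirError):
    """The sample sheet describes an impossible study design
    (unpaired members, duplicate sample ids)."""


class WavelengthRangeError(HemomirError, ValueError):
    """A wavelength falls outside the covered range of a spectrum."""


class InvalidReferenceError(HemomirError, ValueError):
    """A reference absorbance is missing, zero or negative."""


class UndetectedError(HemomirError):
    """An operation that requires detected Cq values received an
    undetected (censored) input."""


class InsufficientDataError(HemomirError):
    """Too few detected points to compute a statistic."""
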