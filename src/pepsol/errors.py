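"""Exception hierarchy.

All package-specific failures derive from :class:`PepsolError` so callers can
catch one base class at API boundaries (the CLI does exactly that).
"""


class PepsolError(Exception):
    """Base class for all errors raised by pepsol."""


class StructureError(PepsolError):
    """A SMILES string could not be parsed, or describes an unusable structure
    (e.g. disconnected fragments where a single molecule is required)."""


class ConfigurationError(PepsolError):
    """An invalid configuration record, e.g. a malformed SMARTS pattern in the
    ionizable-group table. Raised at load time, never at query time."""


class ParameterError(PepsolError):
    """An out-of-range or inconsistent runtime parameter (even smoothing
    window, pH outside [0, 14], ...)."""


class SequenceSyntaxError(PepsolError):
    """A peptide sequence string violates the extended-alphabet grammar."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class ResidueLookupError(PepsolError, KeyError):
    """A residue code is not present in the registry."""


class DuplicateCodeError(PepsolError):
    """Attempt to register a residue code that already exists."""


class RegistryFormatError(PepsolError):
    """A registry file violates the documented JSON schema."""


class UnfittedCalibratorError(PepsolError):
    """A calibrator set was used before its models were fitted."""


class CollinearityError(PepsolError):
    """The design matrix of a linear fit is rank deficient."""

    def __init__(self, message: str, features: list[str] | None = None):
        self.features = features or []
        super().__init__(message)


class MeasurementParseError(PepsolError):
    """A measurements CSV row could not be interpreted."""


class EvaluationError(PepsolError):
    """Not enough usable prediction/measurement pairs to correlate."""
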