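"""Exception hierarchy for the confomer toolkit."""


class ConfomerError(Exception):
    """Base class for all toolkit errors."""


class ParseError(ConfomerError):
    """Raised for syntactically invalid SMILES or unreadable records."""


class ValenceError(ParseError):
    """Raised for chemically impossible structures (valence violations)."""


class EmptyMoleculeError(ConfomerError):
    """Raised when standardization leaves no heavy atom."""


class FormatError(ConfomerError):
    """Raised for unreadable dataset files."""


class MissingLabelError(ConfomerError):
    """Raised when the requested label field is absent from a record."""


class DegenerateDataError(ConfomerError):
    """Raised when a model fit is requested on degenerate data."""


class ConfigError(ConfomerError):
    """Raised for inconsistent nonconformity/model configuration."""


class EmptyCalibrationError(ConfomerError):
    """Raised when a calibration alpha list is empty."""


class InsufficientDataError(ConfomerError):
    """Raised when a dataset is too small for the requested fold split."""


class LengthMismatchError(ConfomerError):
    """Raised when paired sequences differ in length."""


class RenderError(ConfomerError):
    """Raised when a 2D depiction cannot be produced."""
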