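"""Exception hierarchy shared across the package."""


class CardioFuseError(Exception):
    """Base class for package errors."""


class FormatError(CardioFuseError):
    """A file does not conform to its expected dialect."""


class ModalityMissingError(CardioFuseError):
    """A record lacks one of the two required channels (ECG/PCG)."""


class EmptyAnnotationError(CardioFuseError):
    """No usable S1 annotations; the record cannot be beat-segmented."""


class DegenerateSignalError(CardioFuseError):
    """A signal is unusable (e.g. zero variance, too short)."""


class SchemaVersionError(FormatError):
    """A stored archive/checkpoint was written by an unknown schema."""


class ConfigurationError(CardioFuseError):
    """Inconsistent model or pipeline configuration."""


class TrainingError(CardioFuseError):
    """Training failed (e.g. divergent loss)."""
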