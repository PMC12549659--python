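"""Exception hierarchy shared across the pipeline stages."""


class CrispError(Exception):
    """Base class for all package errors."""


class ParseError(CrispError):
    """A record file could not be parsed (names the offending line)."""


class FormatError(CrispError):
    """A file parsed but violates the record format contract."""


class NamingError(CrispError):
    """A walk filename does not follow a recognized convention."""


class IntegrityError(CrispError):
    """Cross-table consistency violation (duplicate ids, missing subjects)."""


class ConfigError(CrispError):
    """Invalid configuration value."""


class TrimError(CrispError):
    """Walk too short for the requested head/tail trim."""


class BalanceError(CrispError):
    """Class balancing impossible (e.g. singleton minority class)."""


class GeometryError(CrispError):
    """A synthetic sample does not lie on its recorded interpolation segment."""


class FitError(CrispError):
    """Model fitting contract violation (e.g. single-class training data)."""


class SchemaError(CrispError):
    """Prediction-time column or label mismatch."""


class SplitError(CrispError):
    """Cross-validation fold construction impossible for the given cohort."""


class AuditError(CrispError):
    """Leakage guard tripped: held-out information touched during fitting."""
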