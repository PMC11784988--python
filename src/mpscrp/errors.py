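"""Exception types raised across the pipeline."""


class MpsCrpError(Exception):
    """Base class for all package errors."""


class ConfigError(MpsCrpError):
    """Invalid or internally inconsistent configuration."""


class SchemaError(MpsCrpError):
    """Input table does not match the expected column schema."""


class DegenerateMatrixError(MpsCrpError):
    """Methylation matrix too sparse or too small for the requested operation."""


class ScoreIncomputableError(MpsCrpError):
    """No overlap between weight-table probes and the methylation matrix."""


class UnidentifiableMixtureError(MpsCrpError):
    """Cell-type reference matrix is rank deficient; proportions not identifiable."""


class DegenerateDesignError(MpsCrpError):
    """Regression design matrix is rank deficient or a predictor is constant."""
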