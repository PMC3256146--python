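"""Exception hierarchy for the isopool package."""


class IsopoolError(Exception):
    """Base class for all package errors."""


class SchemaError(IsopoolError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(IsopoolError):
    """A value violates a field's allowed range; message names field and row."""


class IntegrityError(IsopoolError):
    """Pairing structure is inconsistent (e.g. a pot claimed by two pairs)."""


class EstimationError(IsopoolError):
    """A pool-dilution estimate cannot be formed from the observation."""


class ConfigError(IsopoolError):
    """A simulation or pipeline configuration is invalid."""
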