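"""Exception hierarchy for ccakit.

Every error raised by the package derives from :class:`CcaError` so callers
can catch the package's failures without masking programming errors.
"""


class CcaError(Exception):
    """Base class for all ccakit errors."""


class ConfigurationError(CcaError):
    """A simulation or run configuration field is invalid."""


class FormValidationError(CcaError):
    """A scoring form is malformed (unordered thresholds, wrong count)."""


class MissingDataError(CcaError):
    """A required raw value, error count, or item score is absent."""


class InputShapeError(CcaError):
    """Input has the wrong shape (e.g. not exactly three long-jump trials)."""


class DerivationError(CcaError):
    """Cut-point derivation cannot proceed (empty/degenerate sample)."""


class DiagnosticsError(CcaError):
    """Item diagnostics requested on an empty score set."""


class ReliabilityError(CcaError):
    """ICC estimation cannot proceed (too few pairs, non-finite values)."""


class SelectionError(CcaError):
    """Outcome-item selection is missing a required task."""


class SchemaError(CcaError):
    """A CSV record violates the documented input schema."""
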