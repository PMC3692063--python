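"""Exception hierarchy for the placement pipeline."""


class OrthoplaceError(Exception):
    """Base class for all package errors."""


class LoadError(OrthoplaceError):
    """A mandatory on-disk artifact is missing or unparseable."""


class IntegrityError(OrthoplaceError):
    """Cross-file consistency violated (e.g. tree leaves vs. alignment rows)."""


class QueryValidationError(OrthoplaceError):
    """The query sequence violates length or alphabet constraints."""


class ConfigurationError(OrthoplaceError):
    """A configuration value is out of range or produces a degenerate model."""


class CalibrationError(OrthoplaceError):
    """E-value calibration failed (degenerate score distribution)."""


class GenerationError(OrthoplaceError):
    """The synthetic family generator could not meet its identity targets."""


class FamilySkip(OrthoplaceError):
    """Signal that a family cannot take part in an analysis (too few leaves)."""
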