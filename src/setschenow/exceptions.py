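"""Exception hierarchy for the pipeline."""


class SetschenowError(Exception):
    """Base class for all package-specific errors."""


class InvalidDensityError(SetschenowError):
    """Molar-to-molal conversion hit a non-positive solvent-mass denominator."""


class InsufficientDataError(SetschenowError):
    """Too few points for the requested fit."""


class DegenerateFitError(SetschenowError):
    """Design matrix is singular or the fitted model is physically degenerate."""


class ConfigError(SetschenowError):
    """Run configuration is inconsistent or incomplete."""
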