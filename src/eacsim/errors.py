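"""Exception hierarchy for eacsim."""


class EacsimError(Exception):
    """Base class for all eacsim errors."""


class ParameterDomainError(EacsimError, ValueError):
    """A model parameter is outside its admissible domain."""


class StructuralError(EacsimError, ValueError):
    """The model structure was violated (unknown state, bad ordering)."""


class DemographyError(EacsimError, ValueError):
    """Demographic inputs are malformed or do not cover the requested ages/years."""


class CoverageError(EacsimError, ValueError):
    """Model output does not cover a requested target cell, or grids mismatch."""


class CalibrationError(EacsimError, RuntimeError):
    """The calibration search hit an unrecoverable condition."""


class ConfigError(EacsimError, ValueError):
    """A run configuration failed validation; message lists every problem found."""
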