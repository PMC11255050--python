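"""Exception hierarchy for eatkit."""


class EatkitError(Exception):
    """Base class for all eatkit errors."""


class FormatError(EatkitError):
    """A file does not conform to the expected volumetric format."""


class GeometryError(EatkitError):
    """Masks, grids, or centerlines are geometrically inconsistent."""


class CalibrationError(EatkitError):
    """Missing or invalid tube-voltage calibration entry."""


class PhaseError(EatkitError):
    """An operation was applied to the wrong contrast phase."""


class InputError(EatkitError):
    """Scalar or tabular input violates a precondition."""


class FitError(EatkitError):
    """A statistical model could not be fitted."""


class SpecError(EatkitError):
    """A generator specification is internally inconsistent."""
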