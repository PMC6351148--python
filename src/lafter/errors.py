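"""Exception hierarchy for the lafter package."""


class LafterError(Exception):
    """Base class for all package-specific errors."""


class MapFormatError(LafterError):
    """A density file could not be interpreted as a 3D MRC volume."""


class ValidationError(LafterError):
    """Half-maps and mask are mutually inconsistent (shape, spacing, range)."""


class MaskError(ValidationError):
    """The refinement mask selects no voxels or is out of range."""


class NoResolvableSignalError(LafterError):
    """The half-set FSC is below threshold already in the first shell."""
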