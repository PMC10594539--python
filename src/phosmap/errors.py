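"""Exception types shared across the package."""


class PhosmapError(Exception):
    """Base class for all phosmap errors."""


class ParameterError(PhosmapError, ValueError):
    """A function argument is outside its admissible range."""


class SchemaError(PhosmapError, ValueError):
    """A tabular input is missing required columns or has bad dtypes."""


class ValidationError(PhosmapError, ValueError):
    """Input data violate a domain invariant (e.g. non-finite pRF values)."""


class FitError(PhosmapError, ValueError):
    """A regression could not be computed from degenerate input."""


class DegenerateSurfaceError(PhosmapError, ValueError):
    """The cortical surface is too sparse around a requested vertex."""


class ResolutionError(PhosmapError, ValueError):
    """A stimulus would be rendered below a usable pixel size."""
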