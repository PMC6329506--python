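"""Exception hierarchy for input validation and configuration problems."""


class GrazemapError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(GrazemapError):
    """Raster grids that should share geometry do not."""


class ValidationError(GrazemapError):
    """Input data violates a model precondition."""


class ConfigurationError(GrazemapError):
    """A lookup table or configuration block is incomplete or inconsistent."""


class FixtureError(GrazemapError):
    """A constructed synthetic fixture could not satisfy its contract."""
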