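"""Exception hierarchy shared across shapejam modules."""


class ShapejamError(Exception):
    """Base class for all shapejam errors."""


class InvalidGeometryError(ShapejamError, ValueError):
    """Degenerate polygon or point configuration (zero area, < 3 vertices,
    self-intersection, duplicated points)."""


class DegenerateSampleError(ShapejamError, ValueError):
    """Sample with no usable variability (all values equal, AR̄ = 1, ...)."""


class ParameterDomainError(ShapejamError, ValueError):
    """Parameter outside its mathematical domain (k ≤ 0, α ≤ 0, AR < 1, ...)."""


class NumericalError(ShapejamError, RuntimeError):
    """Quadrature non-convergence, bracket/rejection failure; carries
    diagnostics in ``args``."""


class InsufficientGridError(ShapejamError, ValueError):
    """Parameter grid too sparse for the requested fit range."""


class InputError(ShapejamError, ValueError):
    """Empty or structurally unusable input."""


class SchemaError(ShapejamError, ValueError):
    """On-disk file violates the documented columnar/JSON schema."""


class CoverageError(ShapejamError, ValueError):
    """Polygon/trajectory data does not cover the requested cells or frames."""


class NoCrossoverError(ShapejamError, RuntimeError):
    """MSD curve does not span the ballistic-to-diffusive crossover."""
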