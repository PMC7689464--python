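"""Exception hierarchy shared across the package."""


class VesicleShiftError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VesicleShiftError):
    """Input table columns do not match the declared fraction scheme."""


class DuplicateIdError(VesicleShiftError):
    """A protein accession appears more than once in an input table."""


class DegenerateProfileError(VesicleShiftError):
    """A profile block is all-zero and cannot be normalised."""


class DimensionError(VesicleShiftError):
    """Vector or matrix dimensions are incompatible with the operation."""


class ConfigError(VesicleShiftError):
    """Invalid configuration values."""


class InsufficientMarkersError(VesicleShiftError):
    """Too few marker proteins for a robust estimate."""


class SeparationError(VesicleShiftError):
    """Organelle templates could not be separated to the requested floor."""


class NumericalError(VesicleShiftError):
    """A numerical routine failed (non-finite values, indefinite matrix...)."""
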