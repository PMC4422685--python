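"""Exception hierarchy shared across the package."""


class ApehkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ApehkitError, ValueError):
    """A file could not be parsed in the expected format."""


class RangeError(ApehkitError, ValueError):
    """A residue range or region falls outside the available numbering."""


class GeometryError(ApehkitError, ValueError):
    """Degenerate geometry (coincident points, undefined dihedral, ...)."""


class ConfigurationError(ApehkitError, ValueError):
    """A required residue/atom/region named in a configuration is missing."""


class ClassificationError(ApehkitError, ValueError):
    """A residue in an interaction is not covered by any partition region."""


class ConstructionError(ApehkitError, ValueError):
    """A synthetic design could not be realised geometrically."""


class DataError(ApehkitError, ValueError):
    """An input table is missing required measurements."""
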