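"""Exception types raised across the package."""


class VoxDesignError(Exception):
    """Base class for all package errors."""


class PDBFormatError(VoxDesignError):
    """The input file could not be parsed as PDB."""


class EmptyStructureError(VoxDesignError):
    """No usable residue (complete N/CA/C) was found."""


class DegenerateGeometryError(VoxDesignError):
    """Backbone atoms are collinear or otherwise degenerate."""


class ConfigError(VoxDesignError):
    """A configuration object violates its invariants."""


class ConstraintError(VoxDesignError):
    """A user constraint vector does not match the structure."""
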