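"""Exception hierarchy shared across the package."""


class ScdtrajError(Exception):
    """Base class for all package errors."""


class PDBParseError(ScdtrajError):
    """A PDB record could not be parsed; the message names the line number."""


class StructureError(ScdtrajError):
    """Structurally inconsistent input (atom-count mismatch, empty trajectory...)."""


class SelectionError(ScdtrajError, LookupError):
    """An atom specification matched no atom in the topology."""


class AmbiguousSelectionError(ScdtrajError, LookupError):
    """An atom specification matched more than one atom (add a chain_id)."""


class GeometryError(ScdtrajError):
    """Degenerate geometry: undefined torsion, invalid internal coordinates."""


class RangeError(ScdtrajError, ValueError):
    """Scalar observable outside its documented domain."""


class ConfigError(ScdtrajError, ValueError):
    """Invalid run configuration."""
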