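"""Exception hierarchy shared across the package."""


class TrajnetError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(TrajnetError):
    """A PDB record could not be parsed; message names the offending line."""


class EmptyStructureError(TrajnetError):
    """A structure source yielded zero atoms."""


class TopologyError(TrajnetError):
    """Trajectory models disagree on atom content or ordering."""


class MissingAnchorError(TrajnetError):
    """A residue or ligand rule lacks its anchor atom."""


class SpecError(TrajnetError):
    """A generator or configuration spec violates its invariants."""


class DegenerateSelectionError(TrajnetError):
    """Too few or collinear points: superposition is underdetermined."""


class SelectionError(TrajnetError):
    """An atom/node selection refers to unknown or mismatched entries."""


class NoPathError(TrajnetError):
    """Requested endpoints are not connected in the network."""


class PipelineError(TrajnetError):
    """A pipeline stage failed; message carries the stage name and cause."""
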