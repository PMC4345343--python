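"""Exception hierarchy for the chemomodes pipeline."""


class ChemomodesError(Exception):
    """Base class for all package-specific errors."""


class PDBFormatError(ChemomodesError):
    """File could not be parsed as PDB ATOM/MODEL records."""


class EmptyStructureError(ChemomodesError):
    """A structure with zero ATOM records where at least one was required."""


class SelectionError(ChemomodesError):
    """A residue/chain selection referenced sites absent from the structure."""


class SwapError(ChemomodesError):
    """Chain swapping failed (non-bijective map or heterodimer labels)."""


class InconsistentEnsembleError(ChemomodesError):
    """Frames of an ensemble do not share an identical site list."""


class ComparabilityError(ChemomodesError):
    """Two site sets with differing labels were compared."""


class DimensionError(ChemomodesError):
    """Coordinate arrays of incompatible shapes."""


class ConvergenceError(ChemomodesError):
    """An iterative procedure failed to converge within its budget."""


class InsufficientDataError(ChemomodesError):
    """Too few frames/points for the requested statistic."""


class ValidationError(ChemomodesError):
    """An input matrix or configuration value violated its contract."""


class GeometryError(ChemomodesError):
    """Degenerate geometry (e.g. coincident network sites)."""


class DisconnectedNetworkError(ChemomodesError):
    """Elastic network has floating fragments (more rigid-body zero modes than 6)."""


class UndefinedOverlapError(ChemomodesError):
    """Overlap requested with a zero vector."""


class DegeneratePVError(ChemomodesError):
    """Piston-vector construction found zero displacement on the masked sites."""


class DegenerateDensityError(ChemomodesError):
    """Density-peak analysis on coincident points."""


class ParameterError(ChemomodesError):
    """Out-of-range or inconsistent analysis parameter."""


class UndefinedScoreError(ChemomodesError):
    """Anti-symmetry score requested on a zero-variance distance series."""


class DegenerateGeometryWarning(UserWarning):
    """Superposition target is rank-deficient; the minimizer is not unique."""
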