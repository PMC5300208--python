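"""Exception hierarchy.

Every failure mode of the toolkit raises a subclass of :class:`GagmimicError`
so callers (and the CLI) can catch one base class.  Names mirror the failure
they report, not the module that raises them.
"""


class GagmimicError(Exception):
    """Base class for all gagmimic errors."""


# --- ensemble I/O ---------------------------------------------------------

class PDBParseError(GagmimicError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MalformedEnsembleError(GagmimicError):
    """Model blocks of a multi-model file disagree in atom count or names."""


class IncompleteTableError(GagmimicError):
    """A coordinate table is missing one or more (frame, atom) pairs."""


class DuplicateEntryError(GagmimicError):
    """A table contains a duplicated (frame, atom) pair or residue row."""


class UnknownElementError(GagmimicError):
    """An element symbol has no covalent radius entry."""


# --- selection ------------------------------------------------------------

class EmptyWindowError(GagmimicError):
    """A frame window selects no frames of the trajectory."""


class StrideError(GagmimicError):
    """Requested stride is not an integer multiple of the frame spacing."""


class EmptySelectionError(GagmimicError):
    """An atom selection matched no atoms."""


class SelectionOverlapError(GagmimicError):
    """Ligand and receptor atom sets overlap."""


# --- geometry -------------------------------------------------------------

class DegenerateGeometryError(GagmimicError):
    """Input points are coplanar/collinear where full rank is required."""


class ConvergenceError(GagmimicError):
    """Iterative solver did not converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class InsufficientFramesError(GagmimicError):
    """Operation needs more frames than the ensemble provides."""


class RankError(GagmimicError):
    """Requested more components than the data rank supports."""


# --- clustering -----------------------------------------------------------

class RadiusUnsatisfiableError(GagmimicError):
    """No k <= max_k puts every frame within the RMSD radius of its medoid."""

    def __init__(self, message: str, best_max_distance: float | None = None):
        self.best_max_distance = best_max_distance
        super().__init__(message)


# --- interactions / energetics -------------------------------------------

class MissingBondsError(GagmimicError):
    """Topology has no bonds; run infer_bonds or supply CONECT records."""


class MissingHydrogensError(GagmimicError):
    """Structure has no hydrogens; the H-bond criterion needs them."""


class MissingTotalError(GagmimicError):
    """An energy-decomposition table lacks its TOTAL row."""


# --- assessment -----------------------------------------------------------

class EmptySeriesError(GagmimicError):
    """Summary statistics requested for an empty series."""


class MetricMismatchError(GagmimicError):
    """Two distribution summaries describe different metrics."""


class MissingMetricError(GagmimicError):
    """A verdict requires a metric summary that was not supplied."""


class InvalidEvidenceError(GagmimicError):
    """Docking evidence is unusable (e.g. non-positive reference score)."""


class NothingToCompareError(GagmimicError):
    """All optional comparison components are absent."""


class ReferenceMismatchError(GagmimicError):
    """Reports being ranked were scored against different references."""


# --- synthetic fixtures ---------------------------------------------------

class InfeasibleParametersError(GagmimicError):
    """Generator parameters are geometrically impossible."""
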