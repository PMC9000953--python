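"""Exception hierarchy shared across the pipeline stages."""


class AbcAxisError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(AbcAxisError):
    """A structure or table file could not be parsed."""


class EmptyModelError(AbcAxisError):
    """A structure file contained no atoms."""


class MissingResidueError(AbcAxisError):
    """Residues requested by a stretch selection are absent from the model.

    Attributes
    ----------
    missing : list of (chain_id, res_seq)
        The residue keys that could not be resolved to a CA atom.
    """

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class MissingAtomError(AbcAxisError):
    """A specific atom (e.g. a CA) is absent from the model."""


class PairingError(AbcAxisError):
    """Coordinate lists or residue correspondences could not be paired."""


class DegenerateGeometryError(AbcAxisError):
    """Too few or collinear points for a rigid-body superposition."""


class ShapeError(AbcAxisError):
    """Ensemble members disagree in length or layout."""


class InsufficientEnsembleError(AbcAxisError):
    """Fewer than two structures supplied for essential dynamics."""


class UndefinedCorrelationError(AbcAxisError):
    """Correlation requested for a zero-variance series."""


class RadiiError(AbcAxisError):
    """An element has no van der Waals radius and no fallback is allowed."""


class ParameterError(AbcAxisError):
    """An invalid numerical parameter (probe radius, grid spacing, ...)."""


class MappingError(AbcAxisError):
    """Alignment columns could not be mapped to reference numbering."""


class SpanError(AbcAxisError):
    """A transmembrane span lies outside the mapped reference range."""


class FitError(AbcAxisError):
    """Nonlinear least squares failed to converge."""


class SpecError(AbcAxisError):
    """A synthetic-data specification violates its invariants."""


class EnclosureError(AbcAxisError):
    """A synthetic cavity wall is too sparse to enclose the stated probe."""
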