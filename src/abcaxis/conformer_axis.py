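"""Essential-dynamics PCA of a structure ensemble and the 1-D conformational axis.

The ensemble is an M x 3N matrix: M structures, each contributing the
flattened CA coordinates of its N stretch residues, all expressed in one
common reference frame.  Essential dynamics is the eigendecomposition of the
population covariance of this matrix; the leading eigenvector is the dominant
collective deformation mode, and projecting each structure onto it places the
ensemble on a single "conformational axis" running from the most inward-open
to the most outward-open transporter conformations.

Numerical conventions:

* covariance is normalized by M (population form), the essential-dynamics
  convention, so eigenvalues are reproducible mean squared amplitudes (A^2);
* no mass weighting (CA only, uniform weights);
* eigenvectors are sign-fixed so the first coordinate exceeding 1e-12 in
  magnitude is positive; an optional outward-facing reference structure then
  orients component 1 so that reference projects to the outward (positive)
  extreme;
* degenerate eigenvalues keep the stable (index) order of the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    InsufficientEnsembleError,
    MissingAtomError,
    ShapeError,
    UndefinedCorrelationError,
)
from .structure_io import CoordinateSet, StateLabels, StructureModel


@dataclass
class EnsembleMatrix:
    """M frame-aligned CoordinateSets flattened into an (M, 3N) matrix."""

    entries: list[CoordinateSet]
    matrix: np.ndarray

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[1] // 3

    @property
    def entry_ids(self) -> list[str]:
        return [e.entry_id for e in self.entries]

    @property
    def labels(self) -> list[StateLabels]:
        return [e.labels for e in self.entries]


def build_ensemble(coordsets: list[CoordinateSet],
                   drop_missing: bool = True) -> EnsembleMatrix:
    """Stack frame-aligned CoordinateSets into an ensemble matrix.

    All members must share the same residue count N.  Row i flattens entry i
    as (x1, y1, z1, ..., xN, yN, zN).  Positions flagged missing in any member
    (relaxed-mode CA extraction) are pruned from every member when
    ``drop_missing`` is set; otherwise missing positions raise.
    """
    if len(coordsets) < 2:
        raise InsufficientEnsembleError(
            f"an ensemble needs at least 2 structures; got {len(coordsets)}")
    n0 = len(coordsets[0])
    offenders = [c.entry_id for c in coordsets if len(c) != n0]
    if offenders:
        raise ShapeError(
            f"ensemble members disagree in residue count (expected {n0}): "
            f"{offenders}")

    missing = np.zeros(n0, dtype=bool)
    for c in coordsets:
        if c.missing_mask is not None:
            missing |= c.missing_mask
    if missing.any() and not drop_missing:
        raise ShapeError(
            f"{int(missing.sum())} positions are missing in at least one member "
            "and drop_missing is disabled")

    keep = ~missing
    entries = []
    rows = []
    for c in coordsets:
        kept = CoordinateSet(
            entry_id=c.entry_id, labels=c.labels,
            residue_keys=[k for k, ok in zip(c.residue_keys, keep) if ok],
            coords=c.coords[keep])
        entries.append(kept)
        rows.append(kept.flatten())
    return EnsembleMatrix(entries=entries, matrix=np.asarray(rows, dtype=float))


@dataclass
class EDResult:
    """Essential-dynamics decomposition of an ensemble.

    ``eigenvectors[k]`` is the unit 3N-vector of component k+1; ``projections``
    holds each structure's coordinates along each component (dot product of the
    mean-centered row with the eigenvector), in Angstrom along a unit mode.
    """

    mean: np.ndarray               # (3N,)
    eigenvalues: np.ndarray        # (R,), descending, A^2
    eigenvectors: np.ndarray       # (R, 3N), unit rows
    projections: np.ndarray        # (M, R)
    variance_fraction: np.ndarray  # (R,)
    entry_ids: list[str] = field(default_factory=list)
    labels: list[StateLabels] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _fix_signs(eigvecs: np.ndarray) -> np.ndarray:
    """First coordinate with |v| > 1e-12 made positive, per eigenvector."""
    out = eigvecs.copy()
    for i, v in enumerate(out):
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if len(nz) and v[nz[0]] < 0:
            out[i] = -v
    return out


def essential_dynamics(ensemble: EnsembleMatrix,
                       orient_reference: int | str | None = None) -> EDResult:
    """Eigendecomposition of the covariance of the mean-centered ensemble.

    Computed through the SVD of the centered matrix (numerically equivalent to
    diagonalizing the M-normalized covariance, without forming the 3N x 3N
    matrix).  At most M-1 eigenvalues are nonzero.

    ``orient_reference`` (row index or entry id) names the designated
    outward-facing reference; component 1 is flipped, if needed, so that
    structure sits at the positive (outward) extreme of the axis.
    """
    x = ensemble.matrix
    m = x.shape[0]
    if m < 2:
        raise InsufficientEnsembleError(f"essential dynamics needs M >= 2; got {m}")
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD: xc = u s vt; covariance eigenvalues are s^2 / M
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s ** 2 / m
    eigenvectors = _fix_signs(vt)
    total = eigenvalues.sum()
    variance_fraction = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    projections = xc @ eigenvectors.T

    if orient_reference is not None:
        if isinstance(orient_reference, str):
            try:
                ref = ensemble.entry_ids.index(orient_reference)
            except ValueError:
                raise ShapeError(
                    f"orient_reference {orient_reference!r} not in ensemble") from None
        else:
            ref = int(orient_reference)
        p = projections[:, 0]
        if not np.isclose(p[ref], p.max()) and (
                np.isclose(p[ref], p.min()) or p[ref] < 0):
            eigenvectors[0] = -eigenvectors[0]
            projections[:, 0] = -projections[:, 0]

    return EDResult(mean=mean, eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                    projections=projections, variance_fraction=variance_fraction,
                    entry_ids=list(ensemble.entry_ids), labels=list(ensemble.labels))


def project(ed: EDResult, coord: CoordinateSet, component: int = 1) -> float:
    """Project one frame-aligned structure onto a component (1-based).

    Returns the dot product of (coords - ensemble mean) with the component's
    unit eigenvector, i.e. the structure's coordinate along the axis.
    """
    row = coord.flatten()
    if row.shape != ed.mean.shape:
        raise ShapeError(
            f"coordinate length {row.shape[0]} does not match ensemble 3N = "
            f"{ed.mean.shape[0]}")
    if not 1 <= component <= ed.n_components:
        raise ShapeError(f"component {component} out of range 1..{ed.n_components}")
    return float((row - ed.mean) @ ed.eigenvectors[component - 1])


# ---------------------------------------------------------------------------
# Classification along the axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformationBands:
    """Ordered half-open intervals (lo, hi] labeling the conformational axis.

    Bands run from the most inward to the most outward label; a value exactly
    at a shared edge belongs to the lower (more inward) band.  Values outside
    every interval classify as ``unassigned``.
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        prev = -np.inf
        for label, lo, hi in self.bands:
            if lo >= hi:
                raise ValueError(f"band {label!r} has lo >= hi")
            if lo < prev:
                raise ValueError("bands must be ascending and non-overlapping")
            prev = hi

    @classmethod
    def from_centers(cls, centers: dict[str, float],
                     lower: float = -np.inf, upper: float = np.inf,
                     ) -> "ConformationBands":
        """Bands with edges at midpoints between consecutive band centers."""
        items = sorted(centers.items(), key=lambda kv: kv[1])
        edges = [lower]
        for (_, a), (_, b) in zip(items, items[1:]):
            edges.append((a + b) / 2.0)
        edges.append(upper)
        return cls(tuple((label, edges[i], edges[i + 1])
                         for i, (label, _) in enumerate(items)))

    def classify(self, value: float) -> str:
        for label, lo, hi in self.bands:
            if lo < value <= hi or (lo == -np.inf and value <= hi):
                return label
        return "unassigned"


#: Default axis bands, anchored on where published conformational states
#: cluster on the component-1 axis of the type IV transporter ensemble:
#: inward-facing around -100 (some below -150), occluded/closed around -25,
#: outward-facing between -25 and 0.
DEFAULT_BANDS = ConformationBands.from_centers(
    {"inward": -100.0, "occluded/closed": -25.0, "outward": -5.0})


def classify_conformation(projection: float,
                          bands: ConformationBands = DEFAULT_BANDS) -> str:
    """Label a component-1 value by its axis band (ties go inward)."""
    return bands.classify(float(projection))


# ---------------------------------------------------------------------------
# Alternative residue-pair distance metrics
# ---------------------------------------------------------------------------

@dataclass
class DistanceMetric:
    """Per-structure CA-CA distance between one residue pair."""

    name: str
    pair: tuple[tuple[str, int], tuple[str, int]]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def residue_pair_distance(model: StructureModel,
                          pair: tuple[tuple[str, int], tuple[str, int]]) -> float:
    """Euclidean CA-CA distance (Angstrom) between two residues of a model."""
    ca = model.calpha_map()
    (k1, k2) = pair
    missing = [k for k in (k1, k2) if tuple(k) not in ca]
    if missing:
        raise MissingAtomError(f"model {model.id} has no CA for residue(s) {missing}")
    return float(np.linalg.norm(ca[tuple(k1)] - ca[tuple(k2)]))


def coordset_pair_distance(coord: CoordinateSet,
                           pair: tuple[tuple[str, int], tuple[str, int]]) -> float:
    """CA-CA distance from a CoordinateSet (both keys must be selected)."""
    index = {k: i for i, k in enumerate(coord.residue_keys)}
    missing = [k for k in pair if tuple(k) not in index]
    if missing:
        raise MissingAtomError(
            f"coordinate set {coord.entry_id} lacks residue(s) {missing}")
    (k1, k2) = pair
    return float(np.linalg.norm(coord.coords[index[tuple(k1)]]
                                - coord.coords[index[tuple(k2)]]))


def correlate_axis_with_metric(projections: np.ndarray,
                               metric: DistanceMetric | np.ndarray) -> float:
    """Pearson correlation between component-1 values and a distance metric.

    Inter-residue distances that close up as the transporter opens outward
    (e.g. the NBD-NBD separation) anti-correlate with the axis (r < 0).
    """
    p = np.asarray(projections, dtype=float)
    v = metric.values if isinstance(metric, DistanceMetric) else np.asarray(metric, dtype=float)
    if len(p) != len(v):
        raise ShapeError(f"{len(p)} projections vs {len(v)} metric values")
    if len(p) < 3:
        raise ShapeError(f"need at least 3 structures for a correlation; got {len(p)}")
    if np.ptp(p) == 0 or np.ptp(v) == 0:
        raise UndefinedCorrelationError("one of the series has zero variance")
    return float(stats.pearsonr(p, v).statistic)
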