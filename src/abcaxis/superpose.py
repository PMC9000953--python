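"""Least-squares rigid-body superposition and CA RMSD between conformations.

The transporter comparisons in this package rest on the classical Kabsch
solution: given paired point clouds, the proper rotation R and translation t
minimizing sum ||R x_i + t - y_i||^2 are obtained from the SVD of the
cross-covariance of the centered clouds, with a reflection correction so that
det(R) = +1.

Same-protein comparisons (e.g. closed vs outward conformations of one
transporter) use the unambiguous author-numbering correspondence of CA atoms.
Cross-species comparisons require an explicit residue correspondence; no
automatic structural matching is attempted.

Frame alignment for the conformational-axis analysis superposes each
structure onto a designated reference (historically the outward-facing
Sav1866 model) using only its TM3+TM6 positions, then carries the whole
coordinate set along with that transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PairingError
from .structure_io import CoordinateSet, StructureModel

#: First NBD residue for AtAtm3 (C-terminal of TM6); used by the "nbd" scope.
ATATM3_NBD_START = 461


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform y ~ rotation @ x + translation, plus the residual."""

    rotation: np.ndarray      # (3, 3), proper orthonormal
    translation: np.ndarray   # (3,)
    rmsd: float               # Angstrom, over the paired atoms
    n_pairs: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the transform to an (N, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target : (N, 3) arrays of paired coordinates, N >= 3 and not all
        collinear.

    Returns
    -------
    SuperpositionResult with a proper rotation (det = +1) and the RMSD of the
    transformed mobile cloud against the target.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(mobile) != len(target):
        raise PairingError(
            f"cannot pair {len(mobile)} mobile with {len(target)} target points")
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 pairs; got {n}")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    x = mobile - mc
    y = target - tc
    # collinear clouds leave the rotation about the common axis undetermined
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear; rotation is underdetermined")

    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = tc - rotation @ mc

    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_pairs=n)


def _pair_calpha(model_a: StructureModel, model_b: StructureModel,
                 keys: list[tuple[str, int]] | None) -> tuple[np.ndarray, np.ndarray]:
    ca_a = model_a.calpha_map()
    ca_b = model_b.calpha_map()
    if keys is None:
        keys = [k for k in ca_a if k in ca_b]
    else:
        bad = [k for k in keys if k not in ca_a or k not in ca_b]
        if bad:
            raise PairingError(f"residue keys absent from one model: {bad}")
    if not keys:
        raise PairingError(
            f"no common CA residues between {model_a.id} and {model_b.id}")
    a = np.array([ca_a[k] for k in keys])
    b = np.array([ca_b[k] for k in keys])
    return a, b


def rmsd_between(model_a: StructureModel, model_b: StructureModel,
                 correspondence: list[tuple[str, int]] | None = None,
                 scope: str = "dimer", chain: str | None = None,
                 nbd_start: int = ATATM3_NBD_START) -> float:
    """CA RMSD between two models after optimal superposition.

    ``scope`` selects the residue set when no explicit correspondence is given:

    * ``dimer`` — every CA residue key shared by both models;
    * ``half`` — shared CA keys of a single chain (``chain``, default the
      first chain of ``model_a``);
    * ``nbd`` — shared CA keys with res_seq >= ``nbd_start`` (the
      nucleotide-binding domains, C-terminal of TM6);
    * ``custom`` — requires ``correspondence``.
    """
    if scope == "custom":
        if correspondence is None:
            raise PairingError("scope 'custom' requires an explicit correspondence")
        keys = correspondence
    elif correspondence is not None:
        keys = correspondence
    elif scope == "dimer":
        keys = None
    elif scope == "half":
        ch = chain if chain is not None else model_a.chains[0]
        ca_a, ca_b = model_a.calpha_map(ch), model_b.calpha_map(ch)
        keys = [k for k in ca_a if k in ca_b]
    elif scope == "nbd":
        ca_a, ca_b = model_a.calpha_map(), model_b.calpha_map()
        keys = [k for k in ca_a if k in ca_b and k[1] >= nbd_start]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    a, b = _pair_calpha(model_a, model_b, keys)
    return kabsch_superpose(a, b).rmsd


def align_to_reference(coord: CoordinateSet, frame: CoordinateSet,
                       frame_keys: list[tuple[str, int]] | None = None,
                       coord_keys: list[tuple[str, int]] | None = None) -> CoordinateSet:
    """Transform a whole CoordinateSet by the superposition of a subset.

    The subset (by default every position of ``frame``) of ``coord`` is
    superposed onto ``frame`` and the resulting rigid transform is applied to
    all of ``coord``.  ``frame_keys``/``coord_keys`` give the matched subsets
    when the two structures use different numbering (e.g. aligning a
    transporter's TM3+TM6 stretches onto the reference frame's); they must be
    equally long and ordered consistently.
    """
    if frame_keys is None:
        frame_keys = list(frame.residue_keys)
    if coord_keys is None:
        coord_keys = frame_keys

    if len(frame_keys) != len(coord_keys):
        raise PairingError(
            f"{len(coord_keys)} coordinate keys vs {len(frame_keys)} frame keys")

    frame_index = {k: i for i, k in enumerate(frame.residue_keys)}
    coord_index = {k: i for i, k in enumerate(coord.residue_keys)}
    missing_f = [k for k in frame_keys if k not in frame_index]
    missing_c = [k for k in coord_keys if k not in coord_index]
    if missing_f or missing_c:
        raise PairingError(
            f"frame-subset mismatch; absent from frame: {missing_f}, "
            f"absent from coordinate set: {missing_c}")

    mobile = coord.coords[[coord_index[k] for k in coord_keys]]
    target = frame.coords[[frame_index[k] for k in frame_keys]]
    sup = kabsch_superpose(mobile, target)
    return coord.with_coords(sup.transform(coord.coords))
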