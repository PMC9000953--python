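"""Reading atomic models and moving coordinate/tabular data in and out.

Atomic models come in as PDB or mmCIF (PDBx) files and are reduced to a flat,
immutable-ish :class:`StructureModel`.  The conformational-axis analysis only
ever consumes CA coordinates over declared residue ranges ("stretches"), which
:func:`select_calpha` extracts into a :class:`CoordinateSet`.

Conventions (fixed throughout the package):

* residue numbering is author (PDB ``resSeq``) numbering; ranges are inclusive
  on both ends, matching the "140-160" style used for transporter stretches;
* altloc resolution keeps the highest-occupancy conformer (ties broken by the
  lexicographically first altloc id);
* only model 1 of a multi-model file is used unless another is requested;
* hydrogens are ignored everywhere;
* insertion-code residues are excluded from ranged selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    EmptyModelError,
    MissingResidueError,
    ParseError,
    ShapeError,
)

# Stretch selections for the two transporters whose selections are published.
# Each tuple is an inclusive (start, end) range in author numbering; the ten
# AtAtm3 stretches cover 167 residues spanning the TMD and the NBD.
ATATM3_STRETCHES: tuple[tuple[int, int], ...] = (
    (140, 160), (225, 245), (255, 275), (322, 342), (362, 382),
    (423, 443), (504, 513), (517, 524), (618, 632), (681, 688),
)
NAATM1_STRETCHES: tuple[tuple[int, int], ...] = (
    (36, 56), (107, 127), (137, 157), (204, 224), (244, 264),
    (305, 325), (386, 395), (399, 406), (500, 514), (563, 570),
)

CONFORMATION_STATES = ("inward", "occluded", "closed", "outward", "unassigned")
NUCLEOTIDE_STATES = ("apo", "ATP-or-analog", "ADP", "ADP-VO4", "other")
SUBSTRATE_STATES = ("none", "substrate", "inhibitor")


class Atom(NamedTuple):
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float
    altloc: str


@dataclass(frozen=True)
class StateLabels:
    """Conformation / nucleotide / substrate state of one structure."""

    conformation_state: str = "unassigned"
    nucleotide_state: str = "other"
    substrate_state: str = "none"

    def __post_init__(self):
        if self.conformation_state not in CONFORMATION_STATES:
            raise ValueError(f"unknown conformation state {self.conformation_state!r}")
        if self.nucleotide_state not in NUCLEOTIDE_STATES:
            raise ValueError(f"unknown nucleotide state {self.nucleotide_state!r}")
        if self.substrate_state not in SUBSTRATE_STATES:
            raise ValueError(f"unknown substrate state {self.substrate_state!r}")


@dataclass
class StructureModel:
    """Flat list of heavy atoms from one model of a structure file."""

    id: str
    atoms: list[Atom]
    model_number: int = 1

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinate on atom {a}")
            if not 0.0 <= a.occupancy <= 1.0:
                raise ValueError(f"occupancy outside [0, 1] on atom {a}")
            key = (a.chain_id, a.res_seq, a.icode, a.atom_name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom record {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return tuple(out)

    def calpha_map(self, chain_id: str | None = None) -> dict[tuple[str, int], np.ndarray]:
        """CA coordinates keyed by (chain_id, res_seq); icode residues skipped."""
        out: dict[tuple[str, int], np.ndarray] = {}
        for a in self.atoms:
            if a.atom_name != "CA" or a.element == "H" or a.icode.strip():
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.setdefault((a.chain_id, a.res_seq), np.asarray(a.xyz, dtype=float))
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class StretchSet:
    """Ordered residue intervals defining equivalent positions for one entry.

    Ranges are inclusive on both ends in author numbering and must be
    non-overlapping and ascending.  For the conformational-axis analysis each
    stretch is expected to hold 7-21 residues (``validate_for_axis``).
    """

    entry_id: str
    chain_id: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = None
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"range {start}-{end} has start > end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("ranges must be non-overlapping and ascending")
            prev_end = end

    @property
    def n_residues(self) -> int:
        return sum(end - start + 1 for start, end in self.ranges)

    def residues(self) -> list[int]:
        out: list[int] = []
        for start, end in self.ranges:
            out.extend(range(start, end + 1))
        return out

    def validate_for_axis(self) -> None:
        for start, end in self.ranges:
            n = end - start + 1
            if not 7 <= n <= 21:
                raise ValueError(
                    f"stretch {start}-{end} has {n} residues; the axis analysis "
                    "uses stretches of 7-21 residues"
                )


def parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse a '140-160,225-245' style range list."""
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        lo, _, hi = part.partition("-")
        out.append((int(lo), int(hi if hi else lo)))
    return tuple(out)


@dataclass
class CoordinateSet:
    """Ordered CA coordinates of one structure over its stretch selection."""

    entry_id: str
    labels: StateLabels
    residue_keys: list[tuple[str, int]]
    coords: np.ndarray  # (N, 3) in Angstrom
    missing_mask: np.ndarray | None = None  # True where a CA was absent

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (N, 3); got {self.coords.shape}")
        if len(self.residue_keys) != len(self.coords):
            raise ShapeError(
                f"{len(self.residue_keys)} residue keys but {len(self.coords)} coordinates"
            )

    def __len__(self) -> int:
        return len(self.coords)

    def flatten(self) -> np.ndarray:
        """Row vector (x1, y1, z1, ..., xN, yN, zN)."""
        return self.coords.reshape(-1)

    def with_coords(self, coords: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(self.entry_id, self.labels, list(self.residue_keys),
                             np.asarray(coords, dtype=float), self.missing_mask)


# ---------------------------------------------------------------------------
# Structure reading / writing
# ---------------------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto",
                   model_number: int | None = None) -> StructureModel:
    """Read one model from a PDB or mmCIF file into a :class:`StructureModel`.

    The first model is returned unless ``model_number`` names another.
    Hydrogens are dropped; alternate locations are resolved to the
    highest-occupancy conformer (ties to the lexicographically first altloc).
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}; got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, OSError) as exc:
        if not path.exists():
            raise FileNotFoundError(path) from exc
        raise ParseError(f"could not parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path} contains no models")
    if model_number is None:
        model = st[0]
    else:
        model = next((m for m in st if m.num == model_number), None)
        if model is None:
            raise ParseError(f"{path} has no model number {model_number}")

    # candidate atoms grouped for altloc resolution
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(),
                       res.name, atom.name)
                if key not in groups:
                    groups[key] = []
                    order.append(key)
                groups[key].append(atom)

    atoms: list[Atom] = []
    for key in order:
        cands = groups[key]
        best = min(cands, key=lambda a: (-a.occ, a.altloc or ""))
        chain_id, res_seq, icode, res_name, atom_name = key
        atoms.append(Atom(
            chain_id=chain_id, res_seq=res_seq, icode=icode, res_name=res_name,
            atom_name=atom_name, element=best.element.name,
            xyz=(best.pos.x, best.pos.y, best.pos.z),
            occupancy=min(max(best.occ, 0.0), 1.0), altloc="",
        ))
    if not atoms:
        raise EmptyModelError(f"{path} contains no (non-hydrogen) atoms")
    return StructureModel(id=path.stem, atoms=atoms,
                          model_number=model.num if hasattr(model, "num") else 1)


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a :class:`StructureModel` as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model(model.model_number)
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        rkey = (a.chain_id, a.res_seq, a.res_name)
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            chains[a.chain_id].add_residue(res)
            residues[rkey] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.xyz)
        atom.occ = a.occupancy
        residues[rkey].add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# CA selection
# ---------------------------------------------------------------------------

def select_calpha(model: StructureModel, stretch: StretchSet,
                  labels: StateLabels | None = None,
                  strict: bool = True) -> CoordinateSet:
    """Extract one CA coordinate per stretch residue, in range order.

    In strict mode (default) any residue of the declared ranges lacking a CA
    raises :class:`MissingResidueError` naming the gaps.  With ``strict=False``
    the gaps are zero-filled and flagged in ``missing_mask`` so that ensemble
    construction can honor them.
    """
    if stretch.chain_id not in model.chains:
        raise MissingResidueError(
            f"chain {stretch.chain_id!r} not present in model {model.id} "
            f"(chains: {model.chains})",
            missing=[(stretch.chain_id, r) for r in stretch.residues()],
        )
    ca = model.calpha_map(stretch.chain_id)
    keys = [(stretch.chain_id, r) for r in stretch.residues()]
    missing = [k for k in keys if k not in ca]
    if missing and strict:
        raise MissingResidueError(
            f"model {model.id} lacks CA atoms for {len(missing)} residue(s) of "
            f"the declared ranges: {missing}",
            missing=missing,
        )
    coords = np.zeros((len(keys), 3), dtype=float)
    mask = np.zeros(len(keys), dtype=bool)
    for i, k in enumerate(keys):
        if k in ca:
            coords[i] = ca[k]
        else:
            mask[i] = True
    return CoordinateSet(
        entry_id=model.id,
        labels=labels if labels is not None else StateLabels(),
        residue_keys=keys,
        coords=coords,
        missing_mask=mask if mask.any() else None,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_table(records: Sequence[dict] | pd.DataFrame, path: str | Path,
                format: str = "tsv") -> Path:
    """Write records as TSV (tab delimiter, '.' decimal, header row) or JSON."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"format must be 'tsv' or 'json'; got {format!r}")
    return path


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"format must be 'tsv' or 'json'; got {format!r}")
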