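"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data classes the analysis
consumes:

* CA coordinate ensembles sharing one residue indexing, deformed along a
  small number of orthogonal collective modes with Gaussian amplitudes plus
  isotropic coordinate noise — a stand-in for an ensemble of experimentally
  determined transporter structures;
* hollow atom shells whose enclosed probe-free volume is known analytically —
  fixtures for the cavity flood fill;
* homolog alignments with controlled cysteine placement inside/outside the
  declared transmembrane spans — a stand-in for a blastp-derived homolog set;
* Michaelis-Menten kinetics with multiplicative noise — a stand-in for
  measured ATPase source data.

Every generator is a pure function of its spec including the seed (one
``numpy.random.default_rng`` per call; no global state).

The module-level ``STUDY_*`` defaults pin the generators to the study
conditions of the transporter analysis this package reimplements: an
80-member ensemble whose planted leading mode carries ~62% of the variance,
a 410-sequence homolog alignment with ~0.4% TM cysteine frequency and a
cysteine-free TM6, and ATPase conditions with the published V_max/K_m values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EnclosureError, SpecError
from .kinetics import KineticsDataset
from .structure_io import Atom, CoordinateSet, StateLabels, StructureModel
from .tm_census import Alignment

#: Amino-acid alphabet (one-letter); cysteine handled separately so that
#: cysteine placement is fully controlled by the spec.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NON_CYS = AMINO_ACIDS.replace("C", "")


# ---------------------------------------------------------------------------
# Helix-bundle template
# ---------------------------------------------------------------------------

def make_helix_bundle(n_helices: int = 6, residues_per_helix: int = 21,
                      seed: int = 0, ring_radius: float = 9.0,
                      ) -> tuple[StructureModel, CoordinateSet]:
    """Ideal CA-only helix bundle arranged on a ring.

    Each helix uses canonical alpha-helical CA geometry (1.5 A rise and 100
    degrees of twist per residue on a 2.3 A helical radius), giving the
    familiar ~3.8 A consecutive CA-CA distance.  Helices alternate up/down
    around a ring of ``ring_radius``; the seed sets the azimuthal phase of
    each helix.  Residues are numbered 1..n sequentially on chain A.
    """
    if n_helices < 1 or residues_per_helix < 1:
        raise SpecError("n_helices and residues_per_helix must be positive")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=n_helices)

    rise, twist, helix_r = 1.5, np.deg2rad(100.0), 2.3
    atoms: list[Atom] = []
    num = 0
    for h in range(n_helices):
        ring_angle = 2 * np.pi * h / n_helices
        cx = ring_radius * np.cos(ring_angle)
        cy = ring_radius * np.sin(ring_angle)
        direction = 1.0 if h % 2 == 0 else -1.0
        z0 = -direction * rise * (residues_per_helix - 1) / 2.0
        for i in range(residues_per_helix):
            num += 1
            ang = phases[h] + twist * i
            xyz = (cx + helix_r * np.cos(ang),
                   cy + helix_r * np.sin(ang),
                   z0 + direction * rise * i)
            atoms.append(Atom("A", num, "", "ALA", "CA", "C",
                              tuple(float(v) for v in xyz), 1.0, ""))
    model = StructureModel(id=f"bundle-{n_helices}x{residues_per_helix}-s{seed}",
                           atoms=atoms)
    keys = [("A", a.res_seq) for a in atoms]
    coords = np.array([a.xyz for a in atoms], dtype=float)
    return model, CoordinateSet(model.id, StateLabels(), keys, coords)


# ---------------------------------------------------------------------------
# Conformer ensembles with planted modes
# ---------------------------------------------------------------------------

def random_orthonormal_modes(n_coords: int, k: int, seed: int = 0) -> np.ndarray:
    """k mutually orthogonal unit 3N-vectors from QR of seeded Gaussians."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_coords, k))
    q, _ = np.linalg.qr(g)
    return q.T.copy()


def nbd_separation_mode(template: CoordinateSet,
                        group_a: Sequence[int], group_b: Sequence[int],
                        ) -> np.ndarray:
    """Unit mode translating two residue groups apart along their center line.

    Emulates the dominant inward/outward motion of a transporter: positive
    amplitude moves the groups (e.g. the two nucleotide-binding domains)
    closer together, negative amplitude spreads them — so the centroid
    separation is anti-monotone in the mode coefficient.
    """
    coords = template.coords
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    axis = coords[b].mean(axis=0) - coords[a].mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise SpecError("group centroids coincide; separation axis undefined")
    axis = axis / norm
    mode = np.zeros_like(coords)
    mode[a] = axis       # group A moves toward B for positive coefficients
    mode[b] = -axis
    return (mode / np.linalg.norm(mode)).reshape(-1)


def two_state_label_rule(c: np.ndarray) -> StateLabels:
    """Sign of the mode-1 coefficient: >= 0 outward-like, < 0 inward-like."""
    if c[0] >= 0:
        return StateLabels("outward", "ATP-or-analog", "none")
    return StateLabels("inward", "apo", "none")


@dataclass
class EnsembleSpec:
    """Recipe for a planted-mode conformer ensemble."""

    template: CoordinateSet
    modes: np.ndarray                     # (K, 3N), orthonormal rows
    amplitudes: Sequence[float]           # sigma_k, A
    noise_sigma: float = 0.0              # isotropic per-coordinate noise, A
    m: int = 80
    seed: int = 0
    label_rule: Callable[[np.ndarray], StateLabels] | None = None

    def __post_init__(self):
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        n3 = 3 * len(self.template)
        if self.modes.shape[1] != n3:
            raise SpecError(f"modes have length {self.modes.shape[1]}; template "
                            f"implies 3N = {n3}")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-9):
            raise SpecError("modes must be mutually orthogonal unit vectors")
        if any(s <= 0 for s in self.amplitudes):
            raise SpecError("mode amplitudes must be positive")
        if len(self.amplitudes) != len(self.modes):
            raise SpecError("one amplitude per mode required")
        if self.m < 2:
            raise SpecError("an ensemble needs M >= 2 members")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")


def generate_conformers(spec: EnsembleSpec,
                        coefficients: np.ndarray | None = None,
                        ) -> tuple[list[CoordinateSet], np.ndarray]:
    """Draw M conformers: template + sum_k c_ik mode_k + isotropic noise.

    Mode coefficients c_ik ~ Normal(0, sigma_k^2) unless supplied explicitly.
    Returns the conformers (labels attached per the spec's label rule) and the
    (M, K) ground-truth coefficient matrix.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.modes)
    if coefficients is None:
        coefficients = rng.standard_normal((spec.m, k)) * np.asarray(spec.amplitudes)
    else:
        coefficients = np.asarray(coefficients, dtype=float).reshape(spec.m, k)
    base = spec.template.flatten()
    rule = spec.label_rule if spec.label_rule is not None else two_state_label_rule
    out: list[CoordinateSet] = []
    for i in range(spec.m):
        row = base + coefficients[i] @ spec.modes
        if spec.noise_sigma > 0:
            row = row + rng.normal(0.0, spec.noise_sigma, size=row.shape)
        out.append(CoordinateSet(
            entry_id=f"{spec.template.entry_id}-m{i:03d}",
            labels=rule(coefficients[i]),
            residue_keys=list(spec.template.residue_keys),
            coords=row.reshape(-1, 3)))
    return out, coefficients


#: Study-condition ensemble defaults: 80 members (the size of the published
#: type IV transporter ensemble) on the 6x21 helix bundle (N = 126), three
#: planted modes with SDs 3.0/1.5/1.0 A and 0.0775 A isotropic noise.  By the
#: closed form sigma_1^2 / (sum_k sigma_k^2 + 3N sigma_n^2) the leading mode
#: carries 62% of the expected variance, the share the published ensemble
#: attributes to its first component.
STUDY_ENSEMBLE_M = 80
STUDY_ENSEMBLE_AMPLITUDES = (3.0, 1.5, 1.0)
STUDY_ENSEMBLE_NOISE = 0.0775


def study_ensemble_spec(seed: int = 0) -> EnsembleSpec:
    """EnsembleSpec pinned to the study conditions (see module docstring)."""
    _, template = make_helix_bundle(seed=seed)
    n3 = 3 * len(template)
    modes = random_orthonormal_modes(n3, len(STUDY_ENSEMBLE_AMPLITUDES), seed=seed + 1)
    return EnsembleSpec(template=template, modes=modes,
                        amplitudes=STUDY_ENSEMBLE_AMPLITUDES,
                        noise_sigma=STUDY_ENSEMBLE_NOISE,
                        m=STUDY_ENSEMBLE_M, seed=seed + 2)


def expected_leading_variance_fraction(amplitudes: Sequence[float],
                                       noise_sigma: float, n_residues: int) -> float:
    """Closed-form expected PC1 variance share for a planted-mode ensemble."""
    amps = np.asarray(amplitudes, dtype=float)
    return float(amps[0] ** 2 /
                 (np.sum(amps ** 2) + 3 * n_residues * noise_sigma ** 2))


# ---------------------------------------------------------------------------
# Hollow cavity shells
# ---------------------------------------------------------------------------

def make_cavity_shell(free_radius: float, probe: float = 2.5,
                      wall_atoms: int | None = None, seed: int = 0,
                      vdw_radius: float = 1.70) -> StructureModel:
    """Spherical shell of atoms enclosing an analytically known cavity.

    Atom centers sit on a sphere of radius ``free_radius + vdw_radius`` so
    that the probe-free enclosed region is (to wall-discreteness) the ball of
    radius ``free_radius - probe``, volume (4/3) pi (free_radius - probe)^3.
    The wall density defaults to a spacing fine enough that the largest hole
    (circumradius ~ spacing/sqrt(3)) stays well under the probe reach
    ``vdw_radius + probe``; a wall too sparse to enclose the stated probe
    raises :class:`EnclosureError`.
    """
    if free_radius <= 0:
        raise SpecError("free_radius must be positive")
    shell_r = free_radius + vdw_radius
    reach = vdw_radius + probe
    if wall_atoms is None:
        # nearest-neighbor spacing of n Fibonacci points ~ 3.809 R / sqrt(n);
        # target hole circumradius ~ 0.35 * reach
        target = 0.606 * reach
        wall_atoms = int(np.ceil((3.809 * shell_r / target) ** 2))
    pts = golden_sphere(wall_atoms)
    # seeded random rigid rotation of the lattice
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    pts = pts @ q.T * shell_r

    if wall_atoms >= 2:
        d, _ = cKDTree(pts).query(pts, k=2)
        max_spacing = float(d[:, 1].max())
        if max_spacing / np.sqrt(3.0) >= reach:
            raise EnclosureError(
                f"wall of {wall_atoms} atoms (max spacing {max_spacing:.2f} A) "
                f"cannot enclose a probe of reach {reach:.2f} A")

    atoms = [Atom("A", i + 1, "", "ALA", "CA", "C",
                  tuple(float(v) for v in p), 1.0, "")
             for i, p in enumerate(pts)]
    return StructureModel(id=f"shell-r{free_radius:g}-n{wall_atoms}-s{seed}",
                          atoms=atoms)


def golden_sphere(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points (golden spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def analytic_shell_volume(free_radius: float, probe: float) -> float:
    """Probe-free enclosed volume of an ideal shell: (4/3) pi (R - probe)^3."""
    r = max(free_radius - probe, 0.0)
    return 4.0 / 3.0 * np.pi * r ** 3


# ---------------------------------------------------------------------------
# Homolog alignments with controlled cysteine placement
# ---------------------------------------------------------------------------

@dataclass
class MSASpec:
    """Recipe for a homolog alignment with planted cysteines.

    ``cys_carrier_fractions`` maps reference residue numbers to the fraction
    of homologs carrying a cysteine there.  Substitutions elsewhere never
    introduce cysteines, so cysteine placement is exactly the planted profile.
    """

    n_sequences: int = 410
    length: int = 700
    offset: int = 1                       # number of the first reference residue
    substitution_rate: float = 0.3
    cys_carrier_fractions: Mapping[int, float] = field(default_factory=dict)
    gap_rate: float = 0.0
    seed: int = 0
    reference_id: str = "REF"

    def __post_init__(self):
        if not 0 <= self.substitution_rate <= 1 or not 0 <= self.gap_rate <= 1:
            raise SpecError("rates must lie in [0, 1]")
        for pos, frac in self.cys_carrier_fractions.items():
            if not 0 <= frac <= 1:
                raise SpecError(f"carrier fraction for position {pos} outside [0, 1]")
            if not self.offset <= pos < self.offset + self.length:
                raise SpecError(f"planted position {pos} outside the reference range")
        if self.n_sequences < 1 or self.length < 1:
            raise SpecError("n_sequences and length must be positive")


#: Study-condition cysteine profile: carriers planted at the TM positions the
#: family survey reports (149/215/290/307/405) plus two rare ones, none in
#: TM6.  With the default TM spans the expected TM cysteine frequency is
#: 0.82 carrier-equivalents x 410 / (205 TM columns x 410 cells) = 0.40%.
STUDY_CYS_PROFILE: dict[int, float] = {
    149: 0.20, 160: 0.02, 215: 0.15, 290: 0.10, 307: 0.08, 390: 0.02, 405: 0.25,
}


def study_msa_spec(seed: int = 0) -> MSASpec:
    return MSASpec(n_sequences=410, length=700, offset=1,
                   substitution_rate=0.3,
                   cys_carrier_fractions=dict(STUDY_CYS_PROFILE), seed=seed)


def generate_msa(spec: MSASpec) -> tuple[Alignment, dict[int, float]]:
    """Generate the alignment; returns it with the expected-count ground truth.

    The reference row is cysteine-free; homologs substitute non-cysteine
    residues at ``substitution_rate`` and carry planted cysteines at the
    specified fractions.  Optional gaps are placed in homolog rows only (the
    reference stays ungapped so column numbering is the identity + offset).
    """
    rng = np.random.default_rng(spec.seed)
    non_cys = np.array(list(NON_CYS))
    ref = rng.choice(non_cys, size=spec.length)
    pos_to_col = {spec.offset + i: i for i in range(spec.length)}

    rows: dict[str, str] = {spec.reference_id: "".join(ref)}
    for s in range(spec.n_sequences):
        seq = ref.copy()
        sub = rng.random(spec.length) < spec.substitution_rate
        seq[sub] = rng.choice(non_cys, size=int(sub.sum()))
        if spec.gap_rate > 0:
            gaps = rng.random(spec.length) < spec.gap_rate
            seq[gaps] = "-"
        for pos, frac in spec.cys_carrier_fractions.items():
            if rng.random() < frac:
                seq[pos_to_col[pos]] = "C"
        rows[f"homolog{s:04d}"] = "".join(seq)

    expected = {pos: frac * spec.n_sequences
                for pos, frac in spec.cys_carrier_fractions.items()}
    return Alignment(rows, spec.reference_id), expected


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

#: MgATP concentration grid (mM) spanning well below to well above the K_m
#: range of the study conditions.
DEFAULT_S_GRID = (0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0)

#: Study ATPase conditions: (V_max nmol/min/mg, K_m mM) per condition, as
#: published for the detergent- and nanodisc-solubilized transporter with and
#: without glutathione substrates (K_m is essentially substrate-independent).
STUDY_KINETICS: dict[tuple[str, str], tuple[float, float]] = {
    ("DDM", "none"): (104.0, 0.16),
    ("DDM", "GSSG 2.5 mM"): (117.0, 0.16),
    ("DDM", "GSH 10 mM"): (154.0, 0.16),
    ("nanodisc", "none"): (7.7, 0.08),
    ("nanodisc", "GSSG 2.5 mM"): (32.0, 0.08),
    ("nanodisc", "GSH 10 mM"): (39.0, 0.08),
}


def generate_kinetics(v_max: float, k_m: float,
                      s_grid: Sequence[float] = DEFAULT_S_GRID,
                      noise_sigma: float = 0.05, n_rep: int = 3, seed: int = 0,
                      solubilization: str = "DDM", substrate: str = "none",
                      ) -> KineticsDataset:
    """Noisy Michaelis-Menten measurements at the given condition.

    ``noise_sigma`` is the relative (multiplicative Gaussian) error per
    point — 5% by default, a typical colorimetric-assay repeatability; three
    replicates per concentration mirror the triplicate measurements of the
    study.  ``noise_sigma=0`` puts the points exactly on the curve.
    """
    if v_max <= 0 or k_m <= 0:
        raise SpecError("v_max and k_m must be positive")
    rng = np.random.default_rng(seed)
    s = np.repeat(np.asarray(s_grid, dtype=float), n_rep)
    v_true = v_max * s / (k_m + s)
    v = v_true * (1.0 + noise_sigma * rng.standard_normal(len(s))) \
        if noise_sigma > 0 else v_true
    return KineticsDataset(solubilization=solubilization, substrate=substrate,
                           s=s, v=v)


def study_kinetics_datasets(seed: int = 0, noise_sigma: float = 0.05,
                            ) -> list[KineticsDataset]:
    """All six study ATPase conditions as noisy synthetic datasets."""
    out = []
    for i, ((sol, sub), (vm, km)) in enumerate(STUDY_KINETICS.items()):
        out.append(generate_kinetics(vm, km, noise_sigma=noise_sigma,
                                     seed=seed + i, solubilization=sol,
                                     substrate=sub))
    return out
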