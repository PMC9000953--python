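"""SASA quadrature and cavity flood fill against analytic oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abcaxis.cavity_sasa import (
    RadiiTable,
    cavity_volume,
    compute_sasa,
    golden_spiral_points,
    pocket_asa,
)
from abcaxis.errors import ParameterError, RadiiError
from abcaxis.structure_io import Atom, StructureModel
from abcaxis.synthetic_data import analytic_shell_volume, make_cavity_shell

R_C = 1.70  # carbon vdW radius from the default table
PROBE = 1.4


def atoms_at(points, element="C", res_start=1):
    return [Atom("A", res_start + i, "", "ALA", "CA", element,
                 tuple(float(v) for v in p), 1.0, "")
            for i, p in enumerate(points)]


def model_at(points, **kw):
    return StructureModel("toy", atoms_at(points, **kw))


class TestSasa:
    def test_single_sphere_matches_analytic(self):
        res = compute_sasa(model_at([[0, 0, 0]]), probe=PROBE)
        exact = 4 * np.pi * (R_C + PROBE) ** 2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_are_additive(self):
        res = compute_sasa(model_at([[0, 0, 0], [100, 0, 0]]), probe=PROBE)
        single = compute_sasa(model_at([[0, 0, 0]]), probe=PROBE).total
        assert res.total == pytest.approx(2 * single, rel=1e-9)

    def test_two_overlapping_spheres_closed_form(self):
        # equal inflated radii R at center distance d: each sphere buries a
        # cap of height h = R - d/2, area 2 pi R h
        d = 3.0
        res = compute_sasa(model_at([[0, 0, 0], [d, 0, 0]]), probe=PROBE)
        r = R_C + PROBE
        exact_each = 4 * np.pi * r ** 2 - 2 * np.pi * r * (r - d / 2)
        assert res.per_atom[0] == pytest.approx(exact_each, rel=0.01)
        assert res.per_atom[1] == pytest.approx(exact_each, rel=0.01)

    def test_caged_atom_is_buried(self):
        # surround one atom by a tight shell of neighbors
        cage = make_cavity_shell(free_radius=2.0, probe=1.4, seed=0)
        pts = np.vstack([[0.0, 0.0, 0.0], cage.coords()])
        res = compute_sasa(model_at(pts), probe=PROBE)
        assert res.per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_convergence(self):
        m = model_at([[0, 0, 0], [2.5, 0.7, 0]])
        a = compute_sasa(m, probe=PROBE, n_points=960).total
        b = compute_sasa(m, probe=PROBE, n_points=1920).total
        assert abs(a - b) / b < 0.005

    def test_matches_biotite_with_same_radii(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(6)
        pts = rng.uniform(-4, 4, size=(25, 3))
        ours = compute_sasa(model_at(pts), probe=PROBE, n_points=1920)

        arr = biotite_struc.AtomArray(len(pts))
        arr.coord = pts.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, len(pts) + 1)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = biotite_struc.sasa(arr, probe_radius=PROBE, point_number=1920,
                                    vdw_radii=np.full(len(pts), R_C))
        assert ours.total == pytest.approx(float(theirs.sum()), rel=0.02)

    def test_per_residue_sums_per_atom(self):
        rng = np.random.default_rng(7)
        res = compute_sasa(model_at(rng.uniform(-3, 3, (10, 3))), probe=PROBE)
        assert sum(res.per_residue.values()) == pytest.approx(
            res.per_atom.sum(), abs=1e-6)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-3, 3, (12, 3))
        base = compute_sasa(model_at(pts), probe=PROBE).total
        rot = Rotation.random(random_state=9).as_matrix()
        # the quadrature point set is fixed in the lab frame, so invariance
        # holds to quadrature error, not machine precision
        moved = compute_sasa(model_at(pts @ rot.T + 5.0), probe=PROBE).total
        assert moved == pytest.approx(base, rel=0.01)

    def test_unknown_element_strict_raises(self):
        table = RadiiTable(fallback=None)
        with pytest.raises(RadiiError):
            compute_sasa(model_at([[0, 0, 0]], element="Xx"), radii=table)

    def test_heteroatoms_excluded_by_default(self):
        atoms = atoms_at([[0.0, 0.0, 0.0]])
        atoms.append(Atom("A", 2, "", "POP", "C1", "C", (100.0, 0, 0), 1.0, ""))
        m = StructureModel("het", atoms)
        assert len(compute_sasa(m).per_atom) == 1
        assert len(compute_sasa(m, include_het=True).per_atom) == 2


class TestPocketAsa:
    def test_empty_list_is_zero(self, chain_model):
        assert pocket_asa(chain_model, []) == 0.0

    def test_disjoint_additivity(self, chain_model):
        sasa = compute_sasa(chain_model)
        a = pocket_asa(chain_model, [("A", 1), ("A", 2)], sasa=sasa)
        b = pocket_asa(chain_model, [("A", 10), ("A", 11)], sasa=sasa)
        both = pocket_asa(chain_model, [("A", 1), ("A", 2), ("A", 10), ("A", 11)],
                          sasa=sasa)
        assert both == pytest.approx(a + b, abs=1e-9)

    def test_missing_key(self, chain_model):
        with pytest.raises(KeyError):
            pocket_asa(chain_model, [("Z", 999)])


class TestCavityVolume:
    def test_hollow_shell_matches_analytic(self):
        shell = make_cavity_shell(free_radius=6.0, probe=2.5, seed=1)
        res = cavity_volume(shell, probe=2.5, spacing=0.4)
        assert res.volume == pytest.approx(analytic_shell_volume(6.0, 2.5),
                                           rel=0.10)
        assert res.volume == res.n_cavity_points * 0.4 ** 3

    def test_single_atom_has_no_cavity(self):
        assert cavity_volume(model_at([[0, 0, 0]]), probe=2.5).volume == 0.0

    def test_spacing_convergence(self):
        shell = make_cavity_shell(free_radius=6.0, probe=2.5, seed=2)
        v1 = cavity_volume(shell, probe=2.5, spacing=0.8).volume
        v2 = cavity_volume(shell, probe=2.5, spacing=0.4).volume
        assert abs(v1 - v2) / v2 < 0.05

    def test_probe_monotonicity(self):
        shell = make_cavity_shell(free_radius=6.0, probe=2.5, seed=3)
        volumes = [cavity_volume(shell, probe=p, spacing=0.4).volume
                   for p in (1.4, 2.0, 2.5, 3.0)]
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))

    def test_rotation_invariance_within_grid_jitter(self):
        shell = make_cavity_shell(free_radius=6.0, probe=2.5, seed=4)
        pts = shell.coords()
        vols = []
        for seed in range(5):
            rot = Rotation.random(random_state=seed).as_matrix()
            m = model_at(pts @ rot.T + seed * 1.3)
            vols.append(cavity_volume(m, probe=2.5, spacing=0.4).volume)
        assert (max(vols) - min(vols)) / np.mean(vols) < 0.10

    def test_capped_hull_counts_open_mouth(self):
        # remove a patch of wall: interior-only leaks to zero, capped-hull
        # still reports roughly the enclosed volume
        shell = make_cavity_shell(free_radius=7.0, probe=2.5, seed=5)
        pts = shell.coords()
        keep = pts[:, 2] < 0.55 * pts[:, 2].max()  # open the top
        opened = model_at(pts[keep])
        closed_v = cavity_volume(shell, probe=2.5, spacing=0.4).volume
        interior = cavity_volume(opened, probe=2.5, spacing=0.4).volume
        capped = cavity_volume(opened, probe=2.5, spacing=0.4,
                               bounding_policy="capped-hull").volume
        assert interior < 0.25 * closed_v
        assert capped > 0.5 * closed_v

    def test_parameter_errors(self, chain_model):
        with pytest.raises(ParameterError):
            cavity_volume(chain_model, probe=0.0)
        with pytest.raises(ParameterError):
            cavity_volume(chain_model, spacing=-1.0)
        with pytest.raises(ParameterError):
            cavity_volume(chain_model, bounding_policy="magic")


def test_golden_spiral_is_unit_and_spread():
    pts = golden_spiral_points(500)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    # centroid of a near-uniform spherical point set is near the origin
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01


def test_radii_table():
    t = RadiiTable()
    assert t.resolve("C") == 1.70
    assert t.resolve("s") == 1.80
    assert t.resolve("Fe") == 1.70  # fallback
    with pytest.raises(ValueError):
        RadiiTable(radii={"C": -1.0})
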