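"""Essential-dynamics PCA, axis classification and distance-metric checks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abcaxis.conformer_axis import (
    ConformationBands,
    DistanceMetric,
    build_ensemble,
    classify_conformation,
    coordset_pair_distance,
    correlate_axis_with_metric,
    essential_dynamics,
    project,
    residue_pair_distance,
)
from abcaxis.errors import (
    InsufficientEnsembleError,
    MissingAtomError,
    ShapeError,
    UndefinedCorrelationError,
)
from abcaxis.structure_io import CoordinateSet, StateLabels
from abcaxis.synthetic_data import (
    EnsembleSpec,
    generate_conformers,
    make_helix_bundle,
    nbd_separation_mode,
    random_orthonormal_modes,
    two_state_label_rule,
)
from conftest import random_cloud


def coordset(entry, coords):
    coords = np.asarray(coords, dtype=float)
    keys = [("A", i + 1) for i in range(len(coords))]
    return CoordinateSet(entry, StateLabels(), keys, coords)


class TestBuildEnsemble:
    def test_two_identical_members(self):
        c = coordset("a", random_cloud(5, seed=1))
        ens = build_ensemble([c, coordset("b", c.coords)])
        assert ens.matrix.shape == (2, 15)
        np.testing.assert_array_equal(ens.matrix[0], ens.matrix[1])

    def test_mixed_sizes_name_offender(self):
        sets = [coordset("a", random_cloud(4, 1)), coordset("b", random_cloud(4, 2)),
                coordset("c", random_cloud(5, 3))]
        with pytest.raises(ShapeError, match="c"):
            build_ensemble(sets)

    def test_full_scale_shape(self):
        # M=80 structures x N=167 stretch residues -> 80 x 501 matrix
        rng = np.random.default_rng(9)
        sets = [coordset(f"s{i}", rng.normal(size=(167, 3))) for i in range(80)]
        assert build_ensemble(sets).matrix.shape == (80, 501)

    def test_missing_positions_pruned_consistently(self):
        a = coordset("a", random_cloud(6, 1))
        b = coordset("b", random_cloud(6, 2))
        b.missing_mask = np.array([False, False, True, False, False, False])
        ens = build_ensemble([a, b])
        assert ens.n_residues == 5
        assert all(len(e) == 5 for e in ens.entries)


class TestEssentialDynamics:
    def test_two_member_ensemble_is_rank_one(self):
        ens = build_ensemble([coordset("a", random_cloud(6, 1)),
                              coordset("b", random_cloud(6, 2))])
        ed = essential_dynamics(ens)
        assert ed.eigenvalues[0] > 0
        np.testing.assert_allclose(ed.eigenvalues[1:], 0.0, atol=1e-12)
        assert ed.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_ensemble(self):
        c = coordset("a", random_cloud(5, 1))
        with pytest.raises(InsufficientEnsembleError):
            build_ensemble([c])

    def test_planted_two_mode_recovery(self):
        # sigma1=3, sigma2=1, M=200, no noise: eigenvalue ratio ~ 9 and the
        # leading eigenvector is the planted mode
        _, template = make_helix_bundle(seed=0)
        modes = random_orthonormal_modes(3 * len(template), 2, seed=5)
        spec = EnsembleSpec(template=template, modes=modes, amplitudes=(3.0, 1.0),
                            noise_sigma=0.0, m=200, seed=6)
        sets, _ = generate_conformers(spec)
        ed = essential_dynamics(build_ensemble(sets))
        ratio = ed.eigenvalues[0] / ed.eigenvalues[1]
        assert ratio == pytest.approx(9.0, rel=0.35)  # sampling error at M=200
        assert abs(ed.eigenvectors[0] @ modes[0]) >= 0.99

    def test_eigenvector_orthonormality(self):
        rng = np.random.default_rng(12)
        sets = [coordset(f"s{i}", rng.normal(size=(10, 3))) for i in range(7)]
        ed = essential_dynamics(build_ensemble(sets))
        gram = ed.eigenvectors @ ed.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-9)
        assert np.all(np.diff(ed.eigenvalues) <= 1e-12)
        assert ed.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(15, 12))
        sets = [coordset(f"s{i}", row.reshape(-1, 3)) for i, row in enumerate(x)]
        ed = essential_dynamics(build_ensemble(sets))
        msd = np.mean(np.sum((x - x.mean(0)) ** 2, axis=1))
        assert ed.eigenvalues.sum() == pytest.approx(msd, rel=1e-9)

    def test_matches_covariance_eigendecomposition(self):
        # independent route: eigh of the explicitly formed M-normalized
        # covariance matrix
        rng = np.random.default_rng(14)
        x = rng.normal(size=(9, 12))
        sets = [coordset(f"s{i}", row.reshape(-1, 3)) for i, row in enumerate(x)]
        ed = essential_dynamics(build_ensemble(sets))
        xc = x - x.mean(axis=0)
        w, v = np.linalg.eigh(xc.T @ xc / len(x))
        w, v = w[::-1], v[:, ::-1]
        k = min(len(ed.eigenvalues), 8)  # rank M-1
        np.testing.assert_allclose(ed.eigenvalues[:k], w[:k],
                                   rtol=1e-9, atol=1e-12)
        for i in range(k):
            assert abs(ed.eigenvectors[i] @ v[:, i]) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_duplicate_keeps_axis_direction(self):
        from abcaxis.superpose import align_to_reference
        _, template = make_helix_bundle(seed=1)
        modes = random_orthonormal_modes(3 * len(template), 2, seed=2)
        spec = EnsembleSpec(template=template, modes=modes, amplitudes=(3.0, 1.0),
                            noise_sigma=0.05, m=40, seed=3)
        sets, _ = generate_conformers(spec)
        ed0 = essential_dynamics(build_ensemble(sets))
        # rigidly transform a copy of member 0, realign it into the frame
        rot = Rotation.random(random_state=4).as_matrix()
        moved = sets[0].with_coords(sets[0].coords @ rot.T + np.array([8.0, 1, 2]))
        realigned = align_to_reference(moved, sets[0])
        ed1 = essential_dynamics(build_ensemble(sets + [realigned]))
        assert abs(ed0.eigenvectors[0] @ ed1.eigenvectors[0]) >= 0.999


class TestProjection:
    @pytest.fixture()
    def planted(self):
        _, template = make_helix_bundle(seed=2)
        modes = random_orthonormal_modes(3 * len(template), 2, seed=7)
        spec = EnsembleSpec(template=template, modes=modes, amplitudes=(3.0, 1.0),
                            noise_sigma=0.1, m=60, seed=8)
        sets, coeffs = generate_conformers(spec)
        ens = build_ensemble(sets)
        return ens, essential_dynamics(ens)

    def test_mean_projects_to_zero(self, planted):
        ens, ed = planted
        mean_set = ens.entries[0].with_coords(ed.mean.reshape(-1, 3))
        assert project(ed, mean_set) == pytest.approx(0.0, abs=1e-9)

    def test_eigvec_displacement_projects_to_amplitude(self, planted):
        ens, ed = planted
        c = 4.25
        shifted = ens.entries[0].with_coords(
            (ed.mean + c * ed.eigenvectors[0]).reshape(-1, 3))
        assert project(ed, shifted, component=1) == pytest.approx(c, abs=1e-9)

    def test_projection_variance_equals_eigenvalue(self, planted):
        _, ed = planted
        var = np.mean(ed.projections[:, 0] ** 2)  # population form, mean 0
        assert var == pytest.approx(ed.eigenvalues[0], rel=1e-6)

    def test_length_mismatch(self, planted):
        _, ed = planted
        with pytest.raises(ShapeError):
            project(ed, coordset("x", random_cloud(4, 1)))


class TestClassification:
    def test_default_bands_follow_published_clusters(self):
        assert classify_conformation(-100.0) == "inward"
        assert classify_conformation(-170.0) == "inward"   # widely open inward
        assert classify_conformation(-25.0) == "occluded/closed"
        assert classify_conformation(-10.0) == "outward"

    def test_exact_threshold_goes_inward(self):
        bands = ConformationBands((("inward", -np.inf, -50.0),
                                   ("outward", -50.0, 0.0)))
        assert bands.classify(-50.0) == "inward"
        assert bands.classify(10.0) == "unassigned"

    def test_from_centers_midpoints(self):
        bands = ConformationBands.from_centers({"inward": -100.0, "outward": 0.0})
        assert bands.classify(-51.0) == "inward"
        assert bands.classify(-49.0) == "outward"
        assert bands.classify(-50.0) == "inward"  # tie goes inward

    def test_two_state_synthetic_accuracy_is_perfect(self):
        _, template = make_helix_bundle(seed=3)
        mode = nbd_separation_mode(template, range(0, 42), range(63, 105))
        spec = EnsembleSpec(template=template, modes=mode[None, :],
                            amplitudes=(4.0,), noise_sigma=0.0, m=30, seed=9,
                            label_rule=two_state_label_rule)
        # bimodal coefficients: two well-separated conformational states
        rng = np.random.default_rng(19)
        c = np.concatenate([np.full(15, 4.0), np.full(15, -4.0)])
        sets, coeffs = generate_conformers(
            spec, coefficients=(c + rng.normal(0, 0.3, 30)).reshape(-1, 1))
        ed = essential_dynamics(build_ensemble(sets))
        # orient so that positive c1 (outward-labeled) projects positive
        sign = np.sign(np.corrcoef(coeffs[:, 0], ed.projections[:, 0])[0, 1])
        proj = sign * ed.projections[:, 0]
        out_mean = proj[coeffs[:, 0] >= 0].mean()
        in_mean = proj[coeffs[:, 0] < 0].mean()
        bands = ConformationBands.from_centers(
            {"inward": in_mean, "outward": out_mean})
        predicted = [bands.classify(p) for p in proj]
        truth = [s.labels.conformation_state for s in sets]
        assert predicted == truth  # 100% accuracy on planted labels


class TestDistanceMetrics:
    def test_pair_distance_values(self, chain_model):
        ca = chain_model.calpha_map()
        d = residue_pair_distance(chain_model, (("A", 3), ("A", 17)))
        assert d == pytest.approx(np.linalg.norm(ca[("A", 3)] - ca[("A", 17)]))
        assert residue_pair_distance(chain_model, (("A", 5), ("A", 5))) == 0.0
        with pytest.raises(MissingAtomError):
            residue_pair_distance(chain_model, (("A", 3), ("B", 3)))

    def test_coordset_pair_distance(self):
        c = coordset("a", [[0, 0, 0], [3, 4, 0]])
        assert coordset_pair_distance(c, (("A", 1), ("A", 2))) == pytest.approx(5.0)

    def test_exact_linear_anticorrelation(self):
        p = np.linspace(-100, 0, 12)
        m = DistanceMetric("nbd", (("A", 1), ("B", 1)), -0.3 * p + 40)
        assert correlate_axis_with_metric(p, m) == pytest.approx(-1.0, abs=1e-12)

    def test_independent_metric_is_uncorrelated(self):
        rng = np.random.default_rng(15)
        m = 400
        p = rng.normal(size=m)
        v = rng.normal(size=m)
        assert abs(correlate_axis_with_metric(p, v)) < 2.0 / np.sqrt(m)

    def test_planted_nbd_metric_anticorrelates(self):
        _, template = make_helix_bundle(seed=4)
        a_idx, b_idx = list(range(0, 21)), list(range(42, 63))
        mode = nbd_separation_mode(template, a_idx, b_idx)
        spec = EnsembleSpec(template=template, modes=mode[None, :],
                            amplitudes=(4.0,), noise_sigma=0.1, m=50, seed=10)
        sets, coeffs = generate_conformers(spec)
        ed = essential_dynamics(build_ensemble(sets))
        # separation between the two groups, per structure
        sep = np.array([
            np.linalg.norm(s.coords[a_idx].mean(0) - s.coords[b_idx].mean(0))
            for s in sets])
        # orient the axis with the planted outward direction (positive c1)
        sign = np.sign(np.corrcoef(coeffs[:, 0], ed.projections[:, 0])[0, 1])
        r = correlate_axis_with_metric(sign * ed.projections[:, 0], sep)
        assert r <= -0.9

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_axis_with_metric(np.ones(5), np.arange(5.0))
        with pytest.raises(ShapeError):
            correlate_axis_with_metric(np.arange(2.0), np.arange(2.0))
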