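import numpy as np
import pytest

from morphoface.io import SemilandmarkScheme
from morphoface.procrustes import (
    centroid_size,
    align_pair,
    gpa,
    procrustes_distance,
    bending_energy_matrix,
    slide_semilandmarks,
    _slide_one,
    _center_scale,
)
from morphoface.warping import fit_tps


def rot(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_homogeneity(self, rng):
        cfg = rng.normal(size=(10, 2))
        assert centroid_size(3.7 * cfg) == pytest.approx(3.7 * centroid_size(cfg))

    def test_brute_force_oracle(self, rng):
        cfg = rng.normal(size=(69, 2))
        cen = cfg.mean(axis=0)
        brute = np.sqrt(sum((p[0] - cen[0]) ** 2 + (p[1] - cen[1]) ** 2 for p in cfg))
        assert abs(centroid_size(cfg) - brute) < 1e-12

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            centroid_size(np.ones((5, 2)))


class TestAlignPair:
    def test_identity(self, rng):
        A = rng.normal(size=(7, 2))
        A -= A.mean(axis=0)
        np.testing.assert_allclose(align_pair(A, A), np.eye(2), atol=1e-12)

    def test_recovers_known_rotation(self, rng):
        A = rng.normal(size=(8, 2))
        A -= A.mean(axis=0)
        R = rot(30.0)
        np.testing.assert_allclose(align_pair(A, A @ R), R, atol=1e-10)

    def test_no_reflection(self, rng):
        A = rng.normal(size=(6, 2))
        A -= A.mean(axis=0)
        B = A.copy()
        B[:, 0] = -B[:, 0]  # reflected target
        R = align_pair(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_grid_search_oracle(self, rng):
        """The closed-form rotation beats a fine brute-force angle grid."""
        A = rng.normal(size=(10, 2))
        B = rng.normal(size=(10, 2))
        A -= A.mean(axis=0)
        B -= B.mean(axis=0)
        R = align_pair(A, B)
        obj = ((A @ R - B) ** 2).sum()
        angles = np.deg2rad(np.arange(0.0, 360.0, 0.001))
        cos, sin = np.cos(angles), np.sin(angles)
        # objective(theta) expanded: ||A||^2 + ||B||^2 - 2 (a cos + b sin)
        a = (A * B).sum()
        b = (A[:, 0] * B[:, 1] - A[:, 1] * B[:, 0]).sum()
        objs = (A**2).sum() + (B**2).sum() - 2 * (a * cos + b * sin)
        assert obj <= objs.min() + 1e-6


class TestGPA:
    def test_identical_configs_zero_distance(self, rng):
        base = rng.normal(size=(12, 2))
        configs = []
        for _ in range(5):
            R = rot(rng.uniform(0, 360))
            configs.append(base @ R * rng.uniform(0.5, 2.0) + rng.normal(size=2))
        res = gpa(np.stack(configs))
        assert res.converged
        for i in range(5):
            for j in range(5):
                assert procrustes_distance(res.aligned[i], res.aligned[j]) < 1e-10

    def test_result_invariants(self, rng):
        base = rng.normal(size=(20, 2))
        X = base + rng.normal(scale=0.02, size=(8, 20, 2))
        res = gpa(X)
        np.testing.assert_allclose(res.mean_shape.mean(axis=0), 0, atol=1e-9)
        assert centroid_size(res.mean_shape) == pytest.approx(1.0, abs=1e-9)
        for a in res.aligned:
            np.testing.assert_allclose(a.mean(axis=0), 0, atol=1e-9)
            assert centroid_size(a) == pytest.approx(1.0, abs=1e-9)
        # the renormalized average of the aligned configurations is the mean shape
        avg = res.aligned.mean(axis=0)
        np.testing.assert_allclose(avg / centroid_size(avg), res.mean_shape, atol=1e-8)

    def test_similarity_invariance(self, rng):
        """Random similarity transforms of the inputs leave all pairwise
        Procrustes distances unchanged."""
        X = rng.normal(size=(10, 15, 2))
        res1 = gpa(X)
        Xt = np.empty_like(X)
        for i in range(X.shape[0]):
            Xt[i] = X[i] @ rot(rng.uniform(0, 360)) * rng.uniform(0.2, 5.0) \
                + rng.normal(size=2) * 10
        res2 = gpa(Xt)
        for i in range(X.shape[0]):
            for j in range(i):
                d1 = procrustes_distance(res1.aligned[i], res1.aligned[j])
                d2 = procrustes_distance(res2.aligned[i], res2.aligned[j])
                assert abs(d1 - d2) < 1e-8

    def test_two_triangles_brute_force(self):
        """GPA distance between an equilateral triangle and a 1-degree
        perturbed copy matches brute-force minimization over rotation."""
        eq = np.array([[np.cos(a), np.sin(a)]
                       for a in np.deg2rad([90, 210, 330])])
        pert = np.array([[np.cos(a), np.sin(a)]
                         for a in np.deg2rad([91, 210, 330])])
        res = gpa(np.stack([eq, pert]))
        d_gpa = procrustes_distance(res.aligned[0], res.aligned[1])
        A = _center_scale(eq)
        B = _center_scale(pert)
        angles = np.deg2rad(np.arange(-5, 5, 1e-5))
        best = min(np.linalg.norm(A @ rot(np.rad2deg(t)) - B) for t in angles)
        assert d_gpa == pytest.approx(best, abs=1e-6)


class TestProcrustesDistance:
    def test_zero_and_symmetry(self, rng):
        a = rng.normal(size=(6, 2))
        b = rng.normal(size=(6, 2))
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)

    def test_triangle_inequality(self, rng):
        for _ in range(1000):
            a, b, c = rng.normal(size=(3, 5, 2))
            assert procrustes_distance(a, c) <= (
                procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((3, 2)), np.zeros((4, 2)))


class TestBendingEnergyMatrix:
    def test_affine_null_space(self, rng):
        ref = rng.normal(size=(12, 2))
        M = bending_energy_matrix(ref).matrix
        for d in (np.ones(12), ref[:, 0], ref[:, 1],
                  2.0 + 0.3 * ref[:, 0] - 1.7 * ref[:, 1]):
            assert abs(d @ M @ d) < 1e-9
        np.testing.assert_allclose(M @ np.ones(12), 0, atol=1e-8)
        np.testing.assert_allclose(M @ ref[:, 0], 0, atol=1e-8)
        np.testing.assert_allclose(M @ ref[:, 1], 0, atol=1e-8)

    def test_positive_semidefinite(self, rng):
        for _ in range(5):
            ref = rng.normal(size=(10, 2))
            M = bending_energy_matrix(ref).matrix
            assert np.linalg.eigvalsh(M).min() >= -1e-9

    def test_energy_matches_fitted_tps(self, rng):
        """d' M d equals the w'Kw energy of the explicitly fitted spline."""
        ref = rng.normal(size=(15, 2)) * 2
        bem = bending_energy_matrix(ref)
        d = rng.normal(size=(15, 2)) * 0.1
        t = fit_tps(ref, ref + d)
        assert abs(bem.energy(d) - t.bending_energy) < 1e-8

    def test_coincident_points_raise(self):
        ref = np.array([[0, 0], [0, 0], [1, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="oincident"):
            bending_energy_matrix(ref)


def _toy_scheme():
    """7 points: a 5-point curve (indices 0-4) plus 2 anchors off the curve."""
    return SemilandmarkScheme(
        n_points=7,
        curves=[[0, 1, 2, 3, 4]],
        fixed_indices=[0, 4, 5, 6],
        shape_subset=list(range(7)),
        warp_set=list(range(7)),
    )


def _toy_configs(rng, n):
    base = np.array([[0, 0], [1, 0.1], [2, 0], [3, -0.1], [4, 0],
                     [1, 2], [3, 2]], dtype=float)
    out = []
    for _ in range(n):
        out.append(base + rng.normal(scale=0.05, size=base.shape))
    return np.stack(out)


class TestSliding:
    def test_no_sliding_points_equals_gpa(self, rng):
        scheme = SemilandmarkScheme(n_points=7, curves=[],
                                    fixed_indices=list(range(7)))
        X = _toy_configs(rng, 5)
        slid, res = slide_semilandmarks(X, scheme)
        plain = gpa(X)
        np.testing.assert_array_equal(slid, plain.aligned)

    def test_identical_specimens_zero_displacement(self, rng):
        base = _toy_configs(rng, 1)[0]
        X = np.stack([base] * 4)
        slid, _ = slide_semilandmarks(X, _toy_scheme(), final_gpa=False)
        plain = gpa(X)
        np.testing.assert_allclose(slid, plain.aligned, atol=1e-10)

    def test_energy_non_increasing(self, rng):
        X = _toy_configs(rng, 8)
        trace: list[float] = []
        slide_semilandmarks(X, _toy_scheme(), energy_trace=trace, max_outer_iter=5)
        assert len(trace) >= 2
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_fixed_landmarks_immobile(self, rng):
        X = _toy_configs(rng, 6)
        scheme = _toy_scheme()
        slid, _ = slide_semilandmarks(X, scheme, final_gpa=False)
        plain = gpa(X)
        fixed = scheme.fixed_indices
        np.testing.assert_array_equal(slid[:, fixed, :], plain.aligned[:, fixed, :])

    def test_single_point_grid_search_oracle(self, rng):
        """The closed-form tangent offset of one sliding point matches a
        dense 1-D grid search minimizing bending energy against the mean."""
        from morphoface.procrustes import bending_energy_matrix as bem_f

        scheme = SemilandmarkScheme(
            n_points=7, curves=[[0, 1, 2]], fixed_indices=[0, 2, 3, 4, 5, 6])
        mean = np.array([[0, 0], [1, 0], [2, 0], [0.5, 1], [1.5, 1],
                         [0.5, -1], [1.5, -1]], dtype=float)
        spec = mean.copy()
        spec[1] = [1.07, 0.21]  # displaced sliding point
        M = bem_f(mean).matrix
        slid = _slide_one(spec, mean, M, scheme)
        tangent = spec[2] - spec[0]
        tangent = tangent / np.linalg.norm(tangent)
        offsets = np.arange(-1.0, 1.0, 1e-6)
        # energy(lambda) is quadratic; evaluate on the grid via its terms
        d0 = spec - mean
        t_field = np.zeros_like(spec)
        t_field[1] = tangent
        c0 = (d0[:, 0] @ M @ d0[:, 0] + d0[:, 1] @ M @ d0[:, 1])
        c1 = 2 * (t_field[:, 0] @ M @ d0[:, 0] + t_field[:, 1] @ M @ d0[:, 1])
        c2 = (t_field[:, 0] @ M @ t_field[:, 0] + t_field[:, 1] @ M @ t_field[:, 1])
        energies = c0 + c1 * offsets + c2 * offsets**2
        best = offsets[np.argmin(energies)]
        got = (slid[1] - spec[1]) @ tangent
        assert got == pytest.approx(best, abs=1e-6)

    def test_coincident_neighbors_raise(self):
        scheme = SemilandmarkScheme(n_points=5, curves=[[0, 1, 2]],
                                    fixed_indices=[0, 2, 3, 4])
        X = np.array([[[0, 0], [1, 0], [0, 0], [0, 2], [2, 2]],
                      [[0, 0], [1, .1], [2, 0], [0, 2], [2, 2]]], dtype=float)
        with pytest.raises(ValueError, match="tangent"):
            slide_semilandmarks(X, scheme)
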