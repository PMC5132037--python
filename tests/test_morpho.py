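import numpy as np
import pytest
import scipy.optimize

from ecomorph import (
    SlidingScheme,
    SymmetryMap,
    bending_energy,
    bending_energy_matrix,
    centroid_size,
    gpa,
    procrustes_distance,
    prune_landmarks,
    regress_shape_on_size,
    slide_displacements,
    slide_semilandmarks,
    symmetric_component,
)
from ecomorph.datatypes import SEMILANDMARK, TRUE_LANDMARK, AlignedShapes

from conftest import make_landmarks, random_similarity

TRIANGLE_A = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
TRIANGLE_B = np.array([[0.0, 0.1], [1.2, -0.1], [0.1, 1.1]])


class TestCentroidSize:
    def test_unit_square_hand_value(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        # four corners each 0.5 squared units from the centroid
        assert centroid_size(square) == pytest.approx(np.sqrt(4 * 0.5), abs=1e-12)

    def test_homogeneity_and_translation_invariance(self, rng):
        config = rng.normal(size=(7, 2))
        base = centroid_size(config)
        assert centroid_size(3.0 * config) == pytest.approx(3.0 * base, rel=1e-12)
        assert centroid_size(config + [5.0, -2.0]) == pytest.approx(base, rel=1e-12)

    def test_rotation_invariance(self, rng):
        config = rng.normal(size=(5, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert centroid_size(config @ rot.T) == pytest.approx(
            centroid_size(config), rel=1e-12
        )

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.zeros((4, 2)))


class TestGPA:
    def test_copies_under_similarity_align_identically(self, rng):
        n = 8
        coords = np.stack([random_similarity(rng)(TRIANGLE_A) for _ in range(n)])
        fit = gpa(make_landmarks(coords))
        for i in range(1, n):
            assert np.allclose(fit.coords[i], fit.coords[0], atol=1e-8)
            assert procrustes_distance(fit.coords[i], fit.coords[0]) < 1e-7

    def test_invariant_to_transform_of_one_specimen(self, rng):
        coords = np.stack([TRIANGLE_A, TRIANGLE_B, TRIANGLE_A + 0.1])
        fit1 = gpa(make_landmarks(coords))
        coords2 = coords.copy()
        coords2[1] = random_similarity(rng)(coords2[1])  # not the initialization
        fit2 = gpa(make_landmarks(coords2))
        assert np.allclose(fit1.coords, fit2.coords, atol=1e-8)

    def test_residual_ss_non_increasing(self, rng):
        coords = rng.normal(size=(10, 6, 2)) + np.linspace(0, 5, 6)[None, :, None]
        fit = gpa(make_landmarks(coords))
        diffs = np.diff(fit.residual_ss_history)
        assert np.all(diffs <= 1e-10)

    def test_consensus_invariant_to_specimen_swap(self):
        coords = np.stack([TRIANGLE_A, TRIANGLE_B, TRIANGLE_A * 2 + 1])
        fit1 = gpa(make_landmarks(coords))
        fit2 = gpa(make_landmarks(coords[[0, 2, 1]]))
        assert np.allclose(fit1.consensus, fit2.consensus, atol=1e-9)

    def test_centered_and_unit_size(self):
        coords = np.stack([TRIANGLE_A, TRIANGLE_A + 0.01 * TRIANGLE_B])
        fit = gpa(make_landmarks(coords))
        # tangent projection perturbs size only at second order in shape spread
        for cfg in fit.coords:
            assert np.allclose(cfg.mean(axis=0), 0.0, atol=1e-8)
            assert np.sqrt(np.sum(cfg**2)) == pytest.approx(1.0, abs=1e-6)

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            gpa(make_landmarks(TRIANGLE_A[None]))


class TestProcrustesDistance:
    def test_zero_for_similar_shapes(self, rng):
        other = random_similarity(rng)(TRIANGLE_A)
        assert procrustes_distance(TRIANGLE_A, other) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        d1 = procrustes_distance(TRIANGLE_A, TRIANGLE_B)
        d2 = procrustes_distance(TRIANGLE_B, TRIANGLE_A)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_matches_rotation_grid_oracle(self):
        def oracle(a, b):
            za = a - a.mean(0)
            za /= np.sqrt(np.sum(za**2))
            zb = b - b.mean(0)
            zb /= np.sqrt(np.sum(zb**2))
            best = np.inf
            for theta in np.arange(0.0, 2 * np.pi, 1e-4):
                rot = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                c = np.sum(za * (zb @ rot.T))
                best = min(best, 1.0 - max(c, 0.0) ** 2)
            return np.sqrt(max(best, 0.0))

        d = procrustes_distance(TRIANGLE_A, TRIANGLE_B)
        assert d == pytest.approx(oracle(TRIANGLE_A, TRIANGLE_B), abs=1e-6)

    def test_mismatched_k_raises(self):
        with pytest.raises(ValueError, match="differ"):
            procrustes_distance(TRIANGLE_A, np.zeros((4, 2)))


class TestSymmetricComponent:
    SYM = np.array([[0.0, 1.0], [0.0, -1.0], [-1.0, 0.2], [1.0, 0.2]])
    MAP = SymmetryMap(paired=[(2, 3)], midline=[0, 1])

    def test_symmetric_config_is_fixed_point(self, rng):
        coords = np.stack([self.SYM, random_similarity(rng)(self.SYM)])
        result = symmetric_component(make_landmarks(coords), self.MAP)
        fit = gpa(make_landmarks(coords))
        for i in range(2):
            assert procrustes_distance(result.coords[i], fit.coords[i]) < 1e-8

    def test_output_is_mirror_symmetric(self, rng):
        coords = self.SYM[None] + rng.normal(scale=0.05, size=(4, 4, 2))
        result = symmetric_component(make_landmarks(coords), self.MAP)
        for cfg in result.coords:
            mirrored = cfg.copy()
            mirrored[:, 0] *= -1
            mirrored = mirrored[[0, 1, 3, 2]]
            assert procrustes_distance(cfg, mirrored) < 1e-6

    def test_mirror_duplicate_idempotence(self, rng):
        coords = self.SYM[None] + rng.normal(scale=0.05, size=(3, 4, 2))
        res = symmetric_component(make_landmarks(coords), self.MAP)
        mirrored = coords.copy()
        mirrored[..., 0] *= -1
        mirrored = mirrored[:, [0, 1, 3, 2], :]
        doubled = np.concatenate([coords, mirrored])
        res2 = symmetric_component(make_landmarks(doubled), self.MAP)
        for i in range(3):
            assert procrustes_distance(res.coords[i], res2.coords[i]) < 1e-8
            assert procrustes_distance(res.coords[i], res2.coords[3 + i]) < 1e-8

    def test_hand_built_asymmetric_pair_averaged(self):
        delta = 1e-4
        asym = self.SYM.copy()
        asym[3, 1] += delta  # right member displaced by delta
        coords = np.stack([asym, self.SYM])
        result = symmetric_component(make_landmarks(coords), self.MAP)
        # hand oracle: average the configuration with its aligned mirror copy
        mirrored = asym.copy()
        mirrored[:, 0] *= -1
        mirrored = mirrored[[0, 1, 3, 2]]

        def unitize(x):
            z = x - x.mean(0)
            return z / np.sqrt(np.sum(z**2))

        za, zm = unitize(asym), unitize(mirrored)
        u, _, vt = np.linalg.svd(zm.T @ za)
        if np.linalg.det(u @ vt) < 0:
            u[:, -1] *= -1
        expected = 0.5 * (za + zm @ (u @ vt))
        assert procrustes_distance(result.coords[0], expected) < 1e-6

    def test_incomplete_map_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            symmetric_component(
                make_landmarks(self.SYM[None].repeat(2, 0)),
                SymmetryMap(paired=[(2, 3)], midline=[0]),
            )


class TestBendingEnergy:
    REF = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.4]])

    def test_zero_for_reference_itself(self):
        assert bending_energy(self.REF, self.REF) == pytest.approx(0.0, abs=1e-10)

    def test_zero_for_affine_targets(self, rng):
        shear = np.array([[1.0, 0.7], [0.0, 1.0]])
        target = self.REF @ shear.T + [3.0, -1.0]
        assert bending_energy(self.REF, target) == pytest.approx(0.0, abs=1e-10)
        affine = self.REF @ rng.normal(size=(2, 2)).T + rng.normal(size=2)
        assert bending_energy(self.REF, affine) == pytest.approx(0.0, abs=1e-10)

    def test_matrix_properties(self):
        be = bending_energy_matrix(self.REF)
        assert np.allclose(be, be.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(be) > -1e-10)
        assert np.allclose(be.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(be @ self.REF, 0.0, atol=1e-9)

    def test_matches_interpolation_coefficient_oracle(self):
        # independent route: solve the TPS interpolation system for the
        # warp coefficients w and evaluate the energy quadratic form w' K w
        target = self.REF.copy()
        target[4] += [0.1, -0.2]
        k = self.REF.shape[0]
        d = np.linalg.norm(self.REF[:, None] - self.REF[None, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            kernel = np.where(d > 0, d**2 * np.log(d**2), 0.0)
        q = np.column_stack([np.ones(k), self.REF])
        system = np.block([[kernel, q], [q.T, np.zeros((3, 3))]])
        energy = 0.0
        for dim in range(2):
            sol = np.linalg.solve(system, np.concatenate([target[:, dim], np.zeros(3)]))
            w = sol[:k]
            energy += w @ kernel @ w
        assert bending_energy(self.REF, target) == pytest.approx(energy, abs=1e-8)

    def test_duplicate_landmarks_rejected(self):
        ref = self.REF.copy()
        ref[1] = ref[0]
        with pytest.raises(ValueError, match="duplicate|singular"):
            bending_energy_matrix(ref)


def arc_scheme():
    """7-landmark scheme: 4 true corners + 3 semilandmarks along the top edge."""
    roles = [TRUE_LANDMARK] * 4 + [SEMILANDMARK] * 3
    base = np.array(
        [
            [0.0, 0.0],
            [3.0, 0.0],
            [0.0, 1.0],
            [3.0, 1.0],
            [0.8, 1.1],
            [1.5, 1.2],
            [2.2, 1.1],
        ]
    )
    scheme = SlidingScheme(
        semilandmark_indices=[4, 5, 6],
        neighbors=[(2, 5), (4, 6), (5, 3)],
        iterations=5,
    )
    return base, roles, scheme


class TestSliding:
    def test_zero_iterations_is_identity(self, rng):
        base, roles, scheme = arc_scheme()
        coords = base[None] + rng.normal(scale=0.02, size=(4, 7, 2))
        scheme.iterations = 0
        out = slide_semilandmarks(make_landmarks(coords, roles), scheme)
        assert np.array_equal(out.coords, coords)

    def test_identical_specimens_are_fixed_point(self):
        base, roles, scheme = arc_scheme()
        coords = np.repeat(base[None], 3, axis=0)
        out, log = slide_semilandmarks(
            make_landmarks(coords, roles), scheme, return_diagnostics=True
        )
        # consensus equals every specimen, so deviations (and slides) vanish
        assert np.allclose(out.coords[0], out.coords[1], atol=1e-9)
        for pre, post in log:
            assert post == pytest.approx(0.0, abs=1e-16)

    def test_energy_non_increasing_within_iterations(self, rng):
        base, roles, scheme = arc_scheme()
        coords = base[None] + rng.normal(scale=0.05, size=(6, 7, 2))
        _, log = slide_semilandmarks(
            make_landmarks(coords, roles), scheme, return_diagnostics=True
        )
        assert len(log) == scheme.iterations
        for pre, post in log:
            assert post <= pre + 1e-12

    def test_displacements_match_numerical_minimizer(self, rng):
        base, _, scheme = arc_scheme()
        sem = [4, 5]
        neighbors = [(2, 5), (4, 6)]
        config = base + rng.normal(scale=0.05, size=base.shape)
        reference = base
        t, _ = slide_displacements(config, reference, sem, neighbors)

        be = bending_energy_matrix(reference)
        tangents = np.stack(
            [
                (config[q] - config[p]) / np.linalg.norm(config[q] - config[p])
                for p, q in neighbors
            ]
        )

        def energy(tv):
            x = config.copy()
            x[sem] += tv[:, None] * tangents
            dev = x - reference
            return sum(dev[:, d] @ be @ dev[:, d] for d in range(2))

        res = scipy.optimize.minimize(
            lambda v: energy(v), np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        assert np.allclose(t, res.x, atol=1e-6)

    def test_zero_length_chord_raises(self):
        base, roles, scheme = arc_scheme()
        coords = np.repeat(base[None], 2, axis=0)
        # chord defined by the same landmark on both ends has zero length
        bad = SlidingScheme(semilandmark_indices=[4], neighbors=[(5, 5)], iterations=1)
        with pytest.raises(ValueError, match="zero-length"):
            slide_semilandmarks(make_landmarks(coords, roles), bad)


class TestPruneLandmarks:
    def lpj_like(self, rng):
        roles = [TRUE_LANDMARK] * 6 + [SEMILANDMARK] * 22
        coords = rng.normal(size=(3, 28, 2))
        return make_landmarks(coords, roles)

    def test_jaw_scheme_bookkeeping(self, rng):
        data = self.lpj_like(rng)
        keep = list(range(6)) + [6, 8, 10, 12, 14, 16]  # 6 retained semilandmarks
        pruned = prune_landmarks(data, keep)
        assert pruned.n_landmarks == 12
        assert pruned.roles == [TRUE_LANDMARK] * 6 + [SEMILANDMARK] * 6

    def test_keep_all_is_identity(self, rng):
        data = self.lpj_like(rng)
        out = prune_landmarks(data, list(range(28)))
        assert np.array_equal(out.coords, data.coords)
        assert out.roles == data.roles

    def test_drop_one_per_pair(self, rng):
        # 3 bilateral pairs + 2 midline points; dropping one member per pair
        coords = rng.normal(size=(2, 8, 2))
        data = make_landmarks(coords)
        keep = [0, 2, 4, 6, 7]  # left members + midline
        assert prune_landmarks(data, keep).n_landmarks == 5

    def test_bad_index_raises(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            prune_landmarks(self.lpj_like(rng), [0, 99])


class TestAllometry:
    def _aligned(self, coords, sizes):
        coords = np.asarray(coords, float)
        return AlignedShapes(
            coords=coords,
            centroid_sizes=np.asarray(sizes, float),
            consensus=coords.mean(axis=0),
            iterations_used=1,
        )

    def test_size_independent_shapes(self, rng):
        coords = np.repeat(TRIANGLE_A[None], 20, axis=0)
        sizes = rng.uniform(10, 100, 20)
        res = regress_shape_on_size(self._aligned(coords, sizes))
        assert np.allclose(res.coefficients, 0.0, atol=1e-12)
        assert res.percent_predicted == pytest.approx(0.0, abs=1e-9)

    def test_planted_allometry_recovered(self, rng):
        b = rng.normal(size=6)
        b /= np.linalg.norm(b)
        sizes = rng.uniform(10, 100, 30)
        x = np.log10(sizes)
        coords = (TRIANGLE_A.reshape(-1)[None] + np.outer(x, b)).reshape(30, 3, 2)
        res = regress_shape_on_size(self._aligned(coords, sizes))
        cosine = res.coefficients @ b / np.linalg.norm(res.coefficients)
        assert cosine > 0.999
        assert res.percent_predicted == pytest.approx(100.0, abs=1e-6)

    def test_residuals_orthogonal_to_size(self, rng):
        coords = TRIANGLE_A[None] + rng.normal(scale=0.1, size=(25, 3, 2))
        sizes = rng.uniform(10, 100, 25)
        res = regress_shape_on_size(self._aligned(coords, sizes))
        x = np.log10(sizes)
        xc = x - x.mean()
        assert np.allclose(res.residuals.mean(axis=0), 0.0, atol=1e-9)
        for j in range(res.residuals.shape[1]):
            assert abs(xc @ res.residuals[:, j]) < 1e-9

    def test_constant_size_rejected(self):
        coords = np.repeat(TRIANGLE_A[None], 5, axis=0)
        with pytest.raises(ValueError, match="constant"):
            regress_shape_on_size(self._aligned(coords, np.full(5, 10.0)))
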