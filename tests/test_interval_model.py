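import numpy as np
import pytest
from scipy import sparse

from intervalrt.interval_model import (
    CompressedRadius,
    build_center,
    compress_radius,
    radius_exact,
    radius_from_compressed,
    voxel_covariance_matrix,
)


def random_scenario_matrices(rng, K=5, n=40, m=12, density=0.4):
    return [sparse.random(n, m, density=density, random_state=rng, format="csr") for _ in range(K)]


def random_weights(rng, K):
    w = rng.random(K) + 0.1
    return w / w.sum()


class TestCenter:
    def test_single_scenario_is_identity(self, rng):
        (D,) = random_scenario_matrices(rng, K=1)
        np.testing.assert_allclose(build_center([D], [1.0]).toarray(), D.toarray())

    def test_hand_arithmetic_two_scenarios(self):
        D1, D2 = sparse.csr_matrix([[2.0]]), sparse.csr_matrix([[4.0]])
        Dc = build_center([D1, D2], [0.5, 0.5])
        assert (Dc @ np.ones(1))[0] == pytest.approx(3.0)

    def test_center_dose_is_weighted_mean(self, rng):
        Dks = random_scenario_matrices(rng)
        w = random_weights(rng, len(Dks))
        x = rng.random(Dks[0].shape[1])
        expect = sum(wk * (D @ x) for wk, D in zip(w, Dks))
        np.testing.assert_allclose(build_center(Dks, w) @ x, expect, rtol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        Dks = random_scenario_matrices(rng, K=2)
        Dks[1] = sparse.random(10, 3, density=0.5, format="csr")
        with pytest.raises(ValueError):
            build_center(Dks, [0.5, 0.5])


class TestRadiusExact:
    def test_identical_scenarios_have_zero_radius(self, rng):
        (D,) = random_scenario_matrices(rng, K=1)
        Dks = [D, D, D]
        w = [0.2, 0.3, 0.5]
        Dc = build_center(Dks, w)
        x = rng.random(D.shape[1])
        np.testing.assert_allclose(radius_exact(x, Dks, w, Dc), 0.0, atol=1e-12)

    def test_hand_arithmetic_std(self):
        D1, D2 = sparse.csr_matrix([[2.0]]), sparse.csr_matrix([[4.0]])
        w = [0.5, 0.5]
        Dc = build_center([D1, D2], w)
        # E[d^2] = 10, (E d)^2 = 9 -> std = 1
        assert radius_exact(np.ones(1), [D1, D2], w, Dc)[0] == pytest.approx(1.0)

    def test_positive_homogeneity(self, rng):
        Dks = random_scenario_matrices(rng)
        w = random_weights(rng, len(Dks))
        Dc = build_center(Dks, w)
        x = rng.random(Dks[0].shape[1])
        np.testing.assert_allclose(
            radius_exact(2 * x, Dks, w, Dc), 2 * radius_exact(x, Dks, w, Dc), rtol=1e-12
        )


class TestCompression:
    def test_full_rank_reproduces_exact_radius(self, rng):
        Dks = random_scenario_matrices(rng, K=7)
        w = random_weights(rng, 7)
        Dc = build_center(Dks, w)
        comp = compress_radius(Dks, w, Dc, variance_threshold=1.0)
        for _ in range(20):
            x = rng.random(Dks[0].shape[1])
            re = radius_exact(x, Dks, w, Dc)
            rc = radius_from_compressed(x, comp)
            assert np.linalg.norm(re - rc) <= 1e-10 * np.linalg.norm(re)

    def test_identical_scenarios_compress_to_rank_zero(self, rng):
        (D,) = random_scenario_matrices(rng, K=1)
        Dks = [D, D]
        Dc = build_center(Dks, [0.5, 0.5])
        comp = compress_radius(Dks, [0.5, 0.5], Dc)
        assert comp.rank == 0
        assert comp.variance_explained == 1.0
        np.testing.assert_allclose(comp.radius(np.ones(D.shape[1])), 0.0)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_bad_threshold_raises(self, rng, bad):
        Dks = random_scenario_matrices(rng, K=3)
        w = random_weights(rng, 3)
        Dc = build_center(Dks, w)
        with pytest.raises(ValueError):
            compress_radius(Dks, w, Dc, variance_threshold=bad)

    def test_truncation_decreases_squared_radius_monotonically(self, rng):
        Dks = random_scenario_matrices(rng, K=6)
        w = random_weights(rng, 6)
        Dc = build_center(Dks, w)
        full = compress_radius(Dks, w, Dc, variance_threshold=1.0)
        x = rng.random(Dks[0].shape[1])
        prev = full.radius_sq(x)
        for k in range(full.rank - 1, -1, -1):
            trunc = CompressedRadius(
                sigmas=full.sigmas[:k], modes=full.modes[:k],
                variance_explained=0.0, n_scenarios=full.n_scenarios,
                _n_voxels=Dks[0].shape[0],
            )
            cur = trunc.radius_sq(x)
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_rank_bounded_by_scenario_count(self, rng):
        Dks = random_scenario_matrices(rng, K=4)
        w = random_weights(rng, 4)
        Dc = build_center(Dks, w)
        comp = compress_radius(Dks, w, Dc, variance_threshold=1.0)
        assert comp.rank <= 4

    def test_truncated_error_bounded_by_discarded_variance(self, rng):
        """Mean relative L2 error of the squared radius tracks the tail fraction."""
        Dks = random_scenario_matrices(rng, K=8, n=60, m=15)
        w = random_weights(rng, 8)
        Dc = build_center(Dks, w)
        full = compress_radius(Dks, w, Dc, variance_threshold=1.0)
        total = np.sum(full.sigmas**2)
        k = max(1, full.rank - 3)
        tail = float(np.sum(full.sigmas[k:] ** 2) / total)
        trunc = CompressedRadius(
            sigmas=full.sigmas[:k], modes=full.modes[:k],
            variance_explained=1 - tail, n_scenarios=8, _n_voxels=60,
        )
        ratios = []
        for _ in range(50):
            x = rng.standard_normal(15)
            r2 = radius_exact(x, Dks, w, Dc) ** 2
            ratios.append(np.sum(r2 - trunc.radius_sq(x)) / np.sum(r2))
        assert 0 <= np.mean(ratios) <= tail * 1.5 + 1e-12


class TestCovarianceQuadraticForm:
    def test_explicit_per_voxel_covariance_matches_radius(self, rng):
        """x^T R_i x equals the squared per-voxel radius on a tiny instance."""
        K, n, m = 6, 30, 8
        Dks = random_scenario_matrices(rng, K=K, n=n, m=m, density=0.6)
        w = random_weights(rng, K)
        Dc = build_center(Dks, w)
        x = rng.random(m)
        r2 = radius_exact(x, Dks, w, Dc) ** 2
        dense = [D.toarray() for D in Dks]
        for i in range(n):
            # independent assembly of the covariance-form matrix
            rows = [Dk[i] for Dk in dense]
            ci = sum(wk * r for wk, r in zip(w, rows))
            Ri = sum(wk * np.outer(r, r) for wk, r in zip(w, rows)) - np.outer(ci, ci)
            assert x @ Ri @ x == pytest.approx(r2[i], rel=1e-9, abs=1e-12)
            # the packaged helper agrees with the independent assembly
            np.testing.assert_allclose(voxel_covariance_matrix(Dks, w, i), Ri, atol=1e-12)
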