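"""Outdegree regularization, projection matrix, and quality metrics."""

import numpy as np
import pytest

import prfdecode as pfd
from prfdecode.prf import EncodingMatrix
from prfdecode.reconstruct import OutdegreeMatrix, compute_projection
from prfdecode.stimuli import vectorize_image


@pytest.fixture(scope="module")
def small_W():
    grid = pfd.VisualFieldGrid(20, 20, 10.0)
    pop = pfd.sample_population(60, 6.0, 0.3, seed=31)
    return pfd.build_encoding_matrix(pop.prfs, grid)


class TestOutdegree:
    def test_trace_equals_voxel_count_for_unit_rows(self, small_W):
        D = pfd.compute_outdegree(small_W)
        assert D.d.sum() == pytest.approx(small_W.n_voxels, rel=1e-6)

    def test_matches_per_column_summation_oracle(self, small_W):
        D = pfd.compute_outdegree(small_W)
        oracle = np.array(
            [small_W.W[:, j].sum() for j in range(small_W.n_pixels)]
        )
        floored = np.maximum(oracle, 1e-6 * oracle.max())
        assert np.allclose(D.d, floored)

    def test_uncovered_pixel_gets_epsilon_floor(self):
        grid = pfd.VisualFieldGrid(20, 20, 10.0)
        W = pfd.build_encoding_matrix([pfd.PRFParams(4.0, 4.0, 0.1)], grid)
        D = pfd.compute_outdegree(W)
        assert D.d.min() == pytest.approx(1e-6 * D.d.max())
        assert (D.d > 0).all()

    def test_count_mode_counts_covering_prfs(self, small_W):
        D = pfd.compute_outdegree(small_W, mode="count")
        rowmax = small_W.W.max(axis=1, keepdims=True)
        oracle = (small_W.W > 1e-3 * rowmax).sum(axis=0).astype(float)
        floored = np.maximum(oracle, 1e-6 * oracle.max())
        assert np.allclose(D.d, floored)


class TestProjection:
    def test_identity_closed_form(self):
        # v = p, W = I, D = I  ->  W_VF = I/2
        grid = pfd.VisualFieldGrid(3, 3, 3.0)
        W = EncodingMatrix(W=np.eye(9), grid=grid)
        P = compute_projection(W, OutdegreeMatrix(d=np.ones(9)))
        y = np.arange(9.0)
        assert np.allclose(P.apply(y), y / 2.0)
        assert np.allclose(P.dense(), np.eye(9) / 2.0)

    def test_normal_equation_residual_identity(self, small_W):
        D = pfd.compute_outdegree(small_W)
        P = compute_projection(small_W, D)
        WVF = P.dense()
        A = small_W.W.T @ small_W.W + np.diag(D.d)
        resid = np.linalg.norm(A @ WVF - small_W.W.T)
        assert resid <= 1e-8 * np.linalg.norm(small_W.W.T)

    def test_both_solve_routes_agree(self, small_W):
        import importlib

        R = importlib.import_module("prfdecode.reconstruct")
        D = pfd.compute_outdegree(small_W)
        direct = compute_projection(small_W, D)
        assert direct._route == "direct"
        orig = R.DIRECT_SOLVE_MAX_P
        R.DIRECT_SOLVE_MAX_P = 1
        try:
            wood = compute_projection(small_W, D)
        finally:
            R.DIRECT_SOLVE_MAX_P = orig
        assert wood._route == "woodbury"
        rng = np.random.default_rng(32)
        y = rng.normal(size=small_W.n_voxels)
        assert np.allclose(direct.apply(y), wood.apply(y), atol=1e-10)

    def test_matches_iterative_least_squares_oracle(self, small_W):
        # Eq-style minimization solved independently via LSQR on the
        # augmented system [W; D^(1/2)] x ~ [y; 0]
        from scipy.sparse.linalg import lsqr

        D = pfd.compute_outdegree(small_W)
        P = compute_projection(small_W, D)
        rng = np.random.default_rng(33)
        y = rng.normal(size=small_W.n_voxels)
        A = np.vstack([small_W.W, np.diag(np.sqrt(D.d))])
        b = np.concatenate([y, np.zeros(small_W.n_pixels)])
        x_oracle = lsqr(A, b, atol=1e-12, btol=1e-12, iter_lim=20000)[0]
        x = P.apply(y)
        assert np.linalg.norm(x - x_oracle) <= 1e-6 * max(
            np.linalg.norm(x_oracle), 1.0
        )

    def test_non_spd_system_rejected_with_eigenvalue(self, small_W):
        bad = OutdegreeMatrix(d=np.zeros(small_W.n_pixels))
        with pytest.raises(ValueError, match="positive definite"):
            compute_projection(small_W, bad)

    def test_reconstruct_linear_and_zero(self, small_W):
        D = pfd.compute_outdegree(small_W)
        P = compute_projection(small_W, D)
        rng = np.random.default_rng(34)
        y1 = rng.normal(size=small_W.n_voxels)
        y2 = rng.normal(size=small_W.n_voxels)
        x1 = pfd.reconstruct(P, y1).x
        x2 = pfd.reconstruct(P, y2).x
        combo = pfd.reconstruct(P, 2.0 * y1 - 0.5 * y2).x
        assert np.allclose(combo, 2.0 * x1 - 0.5 * x2, atol=1e-10)
        assert np.allclose(pfd.reconstruct(P, np.zeros(small_W.n_voxels)).x, 0)

    def test_pattern_length_mismatch_rejected(self, small_W):
        P = compute_projection(small_W, pfd.compute_outdegree(small_W))
        with pytest.raises(ValueError, match="length"):
            P.apply(np.zeros(7))

    def test_stronger_regularization_never_grows_reconstruction(self, small_W):
        D = pfd.compute_outdegree(small_W)
        rng = np.random.default_rng(35)
        y = rng.normal(size=small_W.n_voxels)
        norms = []
        for c in (1.0, 2.0, 5.0, 20.0):
            P = compute_projection(small_W, OutdegreeMatrix(d=c * D.d))
            norms.append(np.linalg.norm(P.apply(y)))
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestQualityMetrics:
    def test_first_level_r_extremes(self, letters80):
        img = letters80["T"]
        rec = pfd.ReconstructedImage(
            x=img.pixels.ravel().astype(float), grid=img.grid
        )
        neg = pfd.ReconstructedImage(
            x=-img.pixels.ravel().astype(float), grid=img.grid
        )
        assert pfd.first_level_r(rec, img) == pytest.approx(1.0)
        assert pfd.first_level_r(neg, img) == pytest.approx(-1.0)

    def test_first_level_r_matches_covariance_formula(self, letters80):
        rng = np.random.default_rng(36)
        img = letters80["H"]
        x = rng.normal(size=img.grid.n_pixels)
        r = pfd.first_level_r(x, img)
        a = x - x.mean()
        b = img.pixels.ravel() - img.pixels.mean()
        oracle = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_constant_reconstruction_rejected(self, letters80):
        with pytest.raises(ValueError, match="constant"):
            pfd.first_level_r(np.ones(letters80["H"].grid.n_pixels),
                              letters80["H"])

    def test_second_level_r_perfect_for_identical_sets(self, letters80):
        recons = {
            L: pfd.ReconstructedImage(
                x=img.pixels.ravel().astype(float), grid=img.grid
            )
            for L, img in letters80.items()
        }
        assert pfd.second_level_r(recons, letters80) == pytest.approx(1.0)
        assert pfd.pairwise_correlations(
            {L: i.pixels for L, i in letters80.items()}
        ).shape == (6,)

    def test_second_level_r_near_zero_for_noise(self, letters80):
        rng = np.random.default_rng(37)
        vals = []
        p = letters80["H"].grid.n_pixels
        for _ in range(100):
            recons = {
                L: pfd.ReconstructedImage(
                    x=rng.normal(size=p), grid=letters80[L].grid
                )
                for L in pfd.LETTERS
            }
            vals.append(pfd.second_level_r(recons, letters80))
        assert abs(np.mean(vals)) < 0.1

    def test_fisher_z_is_arctanh(self):
        r = np.array([-0.5, 0.0, 0.8])
        assert np.allclose(pfd.fisher_z(r), np.arctanh(r))


def test_forward_inverse_ranking_small_scale(letters80):
    """Each noiseless reconstruction correlates highest with its own
    generating letter (full-scale fidelity runs in the acceptance suite)."""
    pop = pfd.sample_population(400, 10 / np.sqrt(2), 0.15, seed=38)
    W = pfd.build_encoding_matrix(pop.prfs, letters80["H"].grid)
    P = compute_projection(W, pfd.compute_outdegree(W))
    for L in pfd.LETTERS:
        y = W.W @ vectorize_image(letters80[L]).astype(float)
        rec = pfd.reconstruct(P, y)
        rs = {M: pfd.first_level_r(rec, letters80[M]) for M in pfd.LETTERS}
        assert max(rs, key=rs.get) == L
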