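"""pRF grid search, forward predictions, and the encoding matrix."""

import numpy as np
import pytest

import prfdecode as pfd
from prfdecode.prf import candidate_timecourses, response_matrix
from prfdecode.stimuli import vectorize_image


@pytest.fixture(scope="module")
def small_grid():
    return pfd.build_search_grid(5.0, decay=3.0, n_angles=24, n_ecc=24)


@pytest.fixture(scope="module")
def mapping40():
    grid = pfd.VisualFieldGrid(40, 40, 10.0)
    return pfd.render_bar_apertures(grid, seed=3)


class TestSearchGrid:
    def test_default_candidate_counts(self):
        g = pfd.build_search_grid(5.0)
        assert g.n_locations == 100 * 100
        assert g.slopes.size == 10
        assert g.n_candidates == 100_000

    def test_eccentricity_spacing_strictly_increasing(self):
        g = pfd.build_search_grid(5.0, decay=3.0)
        levels = np.unique(g.ecc)
        assert levels.size == 100
        assert (np.diff(np.diff(levels)) > 0).all()
        assert levels[-1] == pytest.approx(5.0)

    def test_decay_to_zero_approaches_uniform_spacing(self):
        g = pfd.build_search_grid(5.0, decay=1e-6, n_ecc=50, n_angles=4)
        levels = np.unique(g.ecc)
        uniform = np.linspace(0.1, 5.0, 50)
        assert np.allclose(levels, uniform, atol=1e-4)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            pfd.build_search_grid(-1.0)
        with pytest.raises(ValueError):
            pfd.build_search_grid(5.0, decay=0.0)


class TestPredictTimecourse:
    def test_zero_frames_give_zero_series(self, mapping40, hrf):
        blank = pfd.render_bar_apertures(mapping40.grid, seed=3)
        blank.frames = np.zeros_like(blank.frames)
        prf = pfd.PRFParams(1.0, 1.0, 0.5)
        assert np.allclose(pfd.predict_timecourse(prf, blank, hrf), 0.0)

    def test_linear_in_frame_intensity(self, mapping40, hrf):
        prf = pfd.PRFParams(0.5, -1.0, 0.6)
        base = pfd.predict_timecourse(prf, mapping40, hrf)
        doubled = pfd.render_bar_apertures(mapping40.grid, seed=3)
        doubled.frames = mapping40.frames * 2
        assert np.allclose(
            pfd.predict_timecourse(prf, doubled, hrf), 2 * base
        )

    def test_matches_simulator_noiseless_drive(self, mapping40, hrf):
        pop = pfd.sample_population(8, 4.0, 0.3, seed=6)
        sim = pfd.simulate_run(pop, mapping40, hrf, noise_sd=0.0)
        for i, prf in enumerate(pop.prfs):
            pred = pfd.predict_timecourse(prf, mapping40, hrf)
            if pred.std() == 0:
                continue
            pred = (pred - pred.mean()) / pred.std()
            assert np.allclose(sim[i], pred, atol=1e-8)


class TestFitPRFGrid:
    def test_exact_recovery_of_grid_point(self, small_grid, mapping40, hrf):
        j = 4321
        prf = pfd.PRFParams(
            small_grid.x[j], small_grid.y[j], small_grid.sigma[j],
            small_grid.slope[j],
        )
        ts = pfd.predict_timecourse(prf, mapping40, hrf)
        fit = pfd.fit_prf_grid(ts, mapping40, hrf, small_grid)
        assert fit.score == pytest.approx(1.0, abs=1e-9)
        assert fit.best.x0 == pytest.approx(prf.x0)
        assert fit.best.y0 == pytest.approx(prf.y0)
        assert fit.best.slope == prf.slope

    def test_winner_scores_at_least_all_candidates(
        self, small_grid, mapping40, hrf
    ):
        rng = np.random.default_rng(8)
        ts = rng.normal(size=mapping40.n_frames)
        fit = pfd.fit_prf_grid(ts, mapping40, hrf, small_grid)
        P, ok = candidate_timecourses(small_grid, mapping40, hrf)
        obs = (ts - ts.mean()) / np.linalg.norm(ts - ts.mean())
        scores = P[ok] @ obs
        assert fit.score >= scores.max() - 1e-10

    def test_constant_series_flagged_invalid(self, small_grid, mapping40, hrf):
        fit = pfd.fit_prf_grid(
            np.ones(mapping40.n_frames), mapping40, hrf, small_grid
        )
        assert not fit.valid
        assert np.isnan(fit.score)

    def test_offgrid_recovery_within_one_cell(self, small_grid, mapping40, hrf):
        # closed loop with known off-grid ground truth
        rng = np.random.default_rng(9)
        ecc = rng.uniform(0.5, 4.0, size=20)
        ang = rng.uniform(0, 2 * np.pi, size=20)
        prfs = [
            pfd.PRFParams(e * np.cos(a), e * np.sin(a), max(0.3 * e, 0.1), 0.3)
            for e, a in zip(ecc, ang)
        ]
        ts = np.vstack(
            [pfd.predict_timecourse(p, mapping40, hrf) for p in prfs]
        )
        fits = pfd.fit_prf_many(ts, mapping40, hrf, small_grid)
        levels = np.unique(small_grid.ecc)
        n_ok = 0
        for fit, prf in zip(fits, prfs):
            d = np.hypot(fit.best.x0 - prf.x0, fit.best.y0 - prf.y0)
            k = np.searchsorted(levels, prf.eccentricity)
            d_ecc = levels[min(k, levels.size - 1)] - levels[max(k - 1, 0)]
            d_ang = prf.eccentricity * 2 * np.pi / small_grid.n_angles
            n_ok += d <= np.hypot(d_ecc, d_ang)
        assert n_ok >= 19


class TestSelectVoxels:
    def _fits(self, scores):
        return [
            pfd.PRFFit(best=pfd.PRFParams(0, 0, 0.5), score=s, voxel=i)
            for i, s in enumerate(scores)
        ]

    def test_threshold_zero_keeps_all_valid(self):
        fits = self._fits([0.1, 0.5, 0.9])
        assert pfd.select_voxels(fits, 0.0).tolist() == [0, 1, 2]

    def test_retained_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(10)
        fits = self._fits(rng.uniform(-0.2, 1.0, size=200).tolist())
        sizes = [
            len(pfd.select_voxels(fits, th)) for th in (0.0, 0.2, 0.4, 0.6)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            pfd.select_voxels(self._fits([0.1, 0.2]), 0.95)


class TestEncodingMatrix:
    def test_rows_are_unit_sum_gaussians(self, grid80):
        prfs = [pfd.PRFParams(0.0, 0.0, 2.0), pfd.PRFParams(1.0, -2.0, 0.4)]
        W = pfd.build_encoding_matrix(prfs, grid80)
        assert np.allclose(W.W.sum(axis=1), 1.0)
        assert (W.W >= 0).all() and np.isfinite(W.W).all()
        X, Y = grid80.pixel_centers_flat()
        expected = np.exp(-((X - 1.0) ** 2 + (Y + 2.0) ** 2) / (2 * 0.4**2))
        assert np.allclose(W.W[1], expected / expected.sum())

    def test_forward_model_equivalence_with_simulated_drive(
        self, letters80, hrf
    ):
        # W_pRF @ vec(letter) reproduces the noiseless perception pattern
        pop = pfd.sample_population(100, 6.0, 0.25, seed=11, noise_sd=0.0,
                                    imagery_gain=1.0, imagery_noise_sd=0.0)
        W = pfd.build_encoding_matrix(pop.prfs, letters80["H"].grid)
        sim = response_matrix(pop.prfs, letters80["H"].grid)
        for L in pfd.LETTERS:
            v = vectorize_image(letters80[L]).astype(float)
            assert np.allclose(W.W @ v, sim @ v)

    def test_empty_selection_rejected(self, grid80):
        with pytest.raises(ValueError):
            pfd.build_encoding_matrix([], grid80)


def test_parameter_recovery_noiseless_closed_loop(hrf):
    """>=95% of voxels recover location within one grid cell and the exact
    slope from a noiseless mapping run (reduced grid for speed; the
    full-size grid runs in the acceptance suite)."""
    grid = pfd.VisualFieldGrid(40, 40, 10.0)
    frames = pfd.render_bar_apertures(grid, seed=12)
    sgrid = pfd.build_search_grid(10 / np.sqrt(2), n_angles=32, n_ecc=32)
    pop = pfd.sample_population(80, 4.5, 0.3, seed=13)
    ts = pfd.simulate_run(pop, frames, hrf, noise_sd=0.0)
    fits = pfd.fit_prf_many(ts, frames, hrf, sgrid)
    levels = np.unique(sgrid.ecc)
    ok = 0
    for fit, prf in zip(fits, pop.prfs):
        d = np.hypot(fit.best.x0 - prf.x0, fit.best.y0 - prf.y0)
        ecc = prf.eccentricity
        k = np.searchsorted(levels, ecc)
        d_ecc = levels[min(k, levels.size - 1)] - levels[max(k - 1, 0)]
        d_ang = max(ecc, levels[0]) * 2 * np.pi / sgrid.n_angles
        ok += (d <= np.hypot(d_ecc, d_ang) + 1e-9) and (fit.best.slope == 0.3)
    assert ok >= 0.95 * len(fits)
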