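"""Population receptive field model: forward predictions, grid-search
fitting, and the voxel-by-pixel encoding matrix.

Each voxel's pRF is an isotropic 2-D Gaussian with center (x0, y0) and
width sigma tied to eccentricity through a linear slope,
sigma = max(slope * eccentricity, sigma_floor). Fitting is by exhaustive
search over a polar location grid (100 angles x 100 eccentricities whose
density decays exponentially with eccentricity) crossed with 10 slopes,
scoring each candidate by the Pearson correlation between its predicted
and the observed time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemo import HRFSpec, convolve_hrf
from .stimuli import ApertureSequence, VisualFieldGrid

#: default pRF width at fixation, where slope * eccentricity degenerates to 0
SIGMA_FLOOR = 0.1


@dataclass(frozen=True)
class PRFParams:
    """Isotropic Gaussian pRF parameters (degrees of visual angle)."""

    x0: float
    y0: float
    sigma: float
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not np.isfinite(self.eccentricity):
            raise ValueError("pRF center must be finite")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))


def gaussian_field(
    x0, y0, sigma, grid: VisualFieldGrid, normalize: bool = True
) -> np.ndarray:
    """Gaussian pRF profile(s) evaluated at pixel centers, shape (n, p).

    Accepts scalars or equal-length arrays of parameters. With
    ``normalize`` each profile is scaled to unit sum over pixels, fixing
    the arbitrary gain between neural drive and measured z-units.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    X, Y = grid.pixel_centers_flat()
    d2 = (X[None, :] - x0[:, None]) ** 2 + (Y[None, :] - y0[:, None]) ** 2
    G = np.exp(-d2 / (2.0 * sigma[:, None] ** 2))
    if normalize:
        s = G.sum(axis=1, keepdims=True)
        # a pRF entirely off the raster has no pixel support; leave it at 0
        np.divide(G, s, out=G, where=s > 0)
    return G


def response_matrix(
    prfs, grid: VisualFieldGrid, normalize: bool = True
) -> np.ndarray:
    """Stack pRF profiles into the (v, p) forward matrix for a population."""
    x0 = np.asarray([p.x0 for p in prfs])
    y0 = np.asarray([p.y0 for p in prfs])
    sg = np.asarray([p.sigma for p in prfs])
    return gaussian_field(x0, y0, sg, grid, normalize=normalize)


def predict_timecourse(
    prf: PRFParams, frames: ApertureSequence | np.ndarray, hrf: HRFSpec
) -> np.ndarray:
    """Predicted volume series: pRF-frame overlap convolved with the HRF.

    Linear in frame intensity. ``frames`` may be an aperture sequence or a
    raw (T, p) frame matrix on the same grid.
    """
    if not isinstance(frames, ApertureSequence):
        raise TypeError(
            "pass an ApertureSequence (a bare frame matrix has no grid calibration)"
        )
    F = frames.frame_matrix()
    g = gaussian_field(prf.x0, prf.y0, prf.sigma, frames.grid)[0]
    drive = F @ g
    return convolve_hrf(drive, hrf)


# -- search grid -------------------------------------------------------------


@dataclass
class SearchGrid:
    """Candidate pRF models for the grid search.

    ``x``, ``y``, ``ecc``, ``sigma``, ``slope`` are parallel arrays over all
    candidates, sorted lexicographically by (eccentricity, slope, angle) so
    that ties resolve to the smallest eccentricity, then smallest slope.
    """

    x: np.ndarray
    y: np.ndarray
    ecc: np.ndarray
    slope: np.ndarray
    sigma: np.ndarray
    n_angles: int
    n_ecc: int
    slopes: np.ndarray
    decay: float
    ecc_max: float
    sigma_floor: float = SIGMA_FLOOR

    @property
    def n_candidates(self) -> int:
        return self.x.size

    @property
    def n_locations(self) -> int:
        return self.n_angles * self.n_ecc


def build_search_grid(
    ecc_max: float,
    decay: float = 3.0,
    n_angles: int = 100,
    n_ecc: int = 100,
    slopes: np.ndarray | None = None,
    sigma_floor: float = SIGMA_FLOOR,
) -> SearchGrid:
    """Polar candidate grid with exponentially decaying density in
    eccentricity.

    Eccentricity levels are e_k = ecc_max * (exp(decay*k/n) - 1) /
    (exp(decay) - 1), k = 1..n_ecc, so spacing between consecutive levels
    grows with eccentricity (denser sampling near fixation, mirroring
    cortical magnification); as decay -> 0 the levels approach uniform
    spacing. Polar angles are equally spaced on [0, 2*pi).
    """
    if ecc_max <= 0 or decay <= 0:
        raise ValueError("ecc_max and decay must be positive")
    if slopes is None:
        slopes = np.round(np.arange(0.1, 1.001, 0.1), 10)
    slopes = np.asarray(slopes, dtype=float)
    k = np.arange(1, n_ecc + 1)
    ecc_levels = ecc_max * (np.expm1(decay * k / n_ecc)) / np.expm1(decay)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)

    # candidate order: eccentricity-major, then slope, then angle
    E, S, A = np.meshgrid(ecc_levels, slopes, angles, indexing="ij")
    ecc, slope, ang = E.ravel(), S.ravel(), A.ravel()
    return SearchGrid(
        x=ecc * np.cos(ang),
        y=ecc * np.sin(ang),
        ecc=ecc,
        slope=slope,
        sigma=np.maximum(slope * ecc, sigma_floor),
        n_angles=n_angles,
        n_ecc=n_ecc,
        slopes=slopes,
        decay=decay,
        ecc_max=ecc_max,
        sigma_floor=sigma_floor,
    )


# -- fitting -----------------------------------------------------------------


@dataclass
class PRFFit:
    """Winning candidate for one voxel with its correlation score."""

    best: PRFParams
    score: float
    voxel: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not -1.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError("correlation score outside [-1, 1]")


def _standardize_rows(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit norm; flags constant rows."""
    M = M - M.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(M, axis=1)
    ok = norm > 0
    M[ok] /= norm[ok, None]
    return M, ok


def candidate_timecourses(
    grid: SearchGrid,
    frames: ApertureSequence,
    hrf: HRFSpec,
    chunk: int = 8192,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized predicted time courses for every candidate.

    Returns ``(P, ok)`` where P is (n_candidates, T) with zero-mean,
    unit-norm rows and ok flags candidates with nonconstant predictions.
    The HRF is applied to the frame matrix once (convolution and the
    pixel sum commute), so each candidate costs a single mat-vec.
    """
    F = frames.frame_matrix()
    Fh = convolve_hrf(F.T, hrf).T  # (T, p), HRF along time
    n_cand = grid.n_candidates
    P = np.empty((n_cand, Fh.shape[0]))
    for lo in range(0, n_cand, chunk):
        hi = min(lo + chunk, n_cand)
        G = gaussian_field(grid.x[lo:hi], grid.y[lo:hi], grid.sigma[lo:hi],
                           frames.grid)
        P[lo:hi] = G @ Fh.T
    return _standardize_rows(P)


def fit_prf_many(
    ts: np.ndarray,
    frames: ApertureSequence,
    hrf: HRFSpec,
    grid: SearchGrid,
    chunk: int = 8192,
    tie_tol: float = 1e-12,
) -> list[PRFFit]:
    """Grid-search fit for a (v, T) bank of voxel time courses.

    The winning candidate maximizes the Pearson correlation between the
    predicted and observed series; score ties (within ``tie_tol``) resolve
    to the smallest eccentricity, then smallest slope. Voxels with a
    constant observed series are returned with ``valid=False``.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[1] != frames.n_frames:
        raise ValueError(
            f"series length {ts.shape[1]} != frame count {frames.n_frames}"
        )
    obs, obs_ok = _standardize_rows(ts.copy())
    P, cand_ok = candidate_timecourses(grid, frames, hrf, chunk=chunk)

    best_score = np.full(ts.shape[0], -np.inf)
    best_idx = np.zeros(ts.shape[0], dtype=int)
    for lo in range(0, grid.n_candidates, chunk):
        hi = min(lo + chunk, grid.n_candidates)
        R = P[lo:hi] @ obs.T  # (chunk, v) correlations
        R[~cand_ok[lo:hi]] = -np.inf
        # keep the earliest (= smallest ecc/slope) candidate within tie_tol
        cmax = R.max(axis=0)
        improved = cmax > best_score + tie_tol
        first = lo + (R >= cmax[None, :] - tie_tol).argmax(axis=0)
        best_idx[improved] = first[improved]
        best_score[improved] = cmax[improved]

    fits = []
    for i in range(ts.shape[0]):
        j = best_idx[i]
        params = PRFParams(
            x0=grid.x[j], y0=grid.y[j], sigma=grid.sigma[j], slope=grid.slope[j]
        )
        if obs_ok[i]:
            fits.append(PRFFit(best=params, score=float(best_score[i]), voxel=i))
        else:
            fits.append(PRFFit(best=params, score=np.nan, voxel=i, valid=False))
    return fits


def fit_prf_grid(
    ts: np.ndarray, frames: ApertureSequence, hrf: HRFSpec, grid: SearchGrid
) -> PRFFit:
    """Grid-search fit for a single voxel's time course."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1:
        raise ValueError("fit_prf_grid takes one voxel; use fit_prf_many")
    return fit_prf_many(ts[None, :], frames, hrf, grid)[0]


def select_voxels(fits: list[PRFFit], threshold: float = 0.2) -> np.ndarray:
    """Indices of valid fits with score >= threshold.

    The retained count matters downstream (it predicts reconstruction and
    decoding quality), so callers should log ``len(result)``.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    idx = np.asarray(
        [f.voxel for f in fits if f.valid and f.score >= threshold], dtype=int
    )
    if idx.size == 0:
        raise ValueError(
            f"no voxel passed the fit threshold {threshold}; lower the threshold"
        )
    return idx


# -- encoding matrix ---------------------------------------------------------


@dataclass
class EncodingMatrix:
    """Forward matrix W_pRF (v, p): row i is voxel i's unit-sum Gaussian
    profile at pixel centers."""

    W: np.ndarray
    grid: VisualFieldGrid
    voxel_indices: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.W.shape[1] != self.grid.n_pixels:
            raise ValueError("W must be (v, n_pixels) on the stated grid")
        if self.W.shape[0] < 1:
            raise ValueError("need at least one voxel")
        if (self.W < 0).any() or not np.isfinite(self.W).all():
            raise ValueError("W entries must be nonnegative and finite")
        if self.voxel_indices is None:
            self.voxel_indices = np.arange(self.W.shape[0])

    @property
    def n_voxels(self) -> int:
        return self.W.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.W.shape[1]


def build_encoding_matrix(
    fits_or_prfs, grid: VisualFieldGrid, voxel_indices: np.ndarray | None = None
) -> EncodingMatrix:
    """Assemble W_pRF from selected fits (or raw PRFParams)."""
    prfs = [f.best if isinstance(f, PRFFit) else f for f in fits_or_prfs]
    if len(prfs) == 0:
        raise ValueError("need at least one selected voxel")
    W = response_matrix(prfs, grid, normalize=True)
    if voxel_indices is None and fits_or_prfs and isinstance(fits_or_prfs[0], PRFFit):
        voxel_indices = np.asarray([f.voxel for f in fits_or_prfs])
    return EncodingMatrix(W=W, grid=grid, voxel_indices=voxel_indices)
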