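"""Visual-field reconstruction by regularized inversion of the encoding
matrix, and first/second-level quality metrics.

The reconstruction x of a voxel pattern y minimizes

    E = (y - W x)^T (y - W x) + x^T D x,

where W is the (v, p) pRF encoding matrix and D a diagonal matrix of
pixel outdegrees (the total encoding mass each pixel projects to cortex, a
cortical-magnification proxy): well-covered pixels are penalized more, and
pixels outside every pRF shrink to zero. The minimizer is

    x = (W^T W + D)^(-1) W^T y = W_VF y.

For the 150x150 raster (p = 22500) the p-by-p normal matrix is never
formed; the algebraically identical form
W_VF = D^(-1) W^T (I_v + W D^(-1) W^T)^(-1) reduces the factorization to a
v-by-v symmetric positive-definite Cholesky solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .patterns import VoxelPattern
from .prf import EncodingMatrix
from .stimuli import LETTERS, LetterImage, VisualFieldGrid, devectorize_image

#: epsilon floor on outdegrees, as a fraction of the largest outdegree
OUTDEGREE_FLOOR_FRAC = 1e-6

#: below this pixel count the direct p-by-p SPD solve is used
DIRECT_SOLVE_MAX_P = 3000


@dataclass
class OutdegreeMatrix:
    """Diagonal pixel-outdegree regularizer, stored as its diagonal."""

    d: np.ndarray
    mode: str = "mass"  # mass | count

    def __post_init__(self) -> None:
        if self.d.ndim != 1:
            raise ValueError("outdegree diagonal must be a vector")
        if (self.d < 0).any():
            raise ValueError("outdegrees must be nonnegative")


def compute_outdegree(
    W: EncodingMatrix,
    mode: str = "mass",
    count_threshold: float = 1e-3,
    floor_frac: float = OUTDEGREE_FLOOR_FRAC,
) -> OutdegreeMatrix:
    """Pixel outdegrees: column mass of W_pRF (default), or the count of
    pRFs covering the pixel above ``count_threshold`` of their row maximum.

    A floor of ``floor_frac * max(d)`` keeps every diagonal entry positive
    so that (W^T W + D) stays positive definite; pixels with no coverage
    then shrink to zero in the reconstruction.
    """
    if mode == "mass":
        d = W.W.sum(axis=0)
    elif mode == "count":
        rowmax = W.W.max(axis=1, keepdims=True)
        d = (W.W > count_threshold * rowmax).sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown outdegree mode {mode!r}")
    floor = floor_frac * d.max()
    return OutdegreeMatrix(d=np.maximum(d, floor), mode=mode)


@dataclass
class ProjectionMatrix:
    """W_VF = (W^T W + D)^(-1) W^T held in factored form.

    ``apply`` reconstructs patterns without materializing the (p, v)
    matrix; ``dense`` materializes it when p and v are small.
    """

    W: np.ndarray  # (v, p)
    d: np.ndarray  # (p,)
    _route: str
    _factor: tuple
    grid: VisualFieldGrid | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.W.shape[1], self.W.shape[0])

    def apply(self, y: np.ndarray) -> np.ndarray:
        """W_VF @ y for a single pattern (v,) or a stack (n, v) -> (n, p)."""
        y = np.asarray(y, dtype=float)
        single = y.ndim == 1
        Y = np.atleast_2d(y)
        if Y.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"pattern length {Y.shape[1]} != voxel count {self.W.shape[0]}"
            )
        if self._route == "direct":
            X = cho_solve(self._factor, self.W.T @ Y.T).T
        else:
            Z = cho_solve(self._factor, Y.T)  # (v, n)
            X = ((self.W.T @ Z) / self.d[:, None]).T
        return X[0] if single else X

    def dense(self) -> np.ndarray:
        return self.apply(np.eye(self.W.shape[0])).T


def compute_projection(
    W: EncodingMatrix, D: OutdegreeMatrix
) -> ProjectionMatrix:
    """Factor the regularized normal equations once per ROI/subject.

    Uses a direct Cholesky of (W^T W + D) when p is small, otherwise the
    v-by-v identity form (see module docstring); both are exact solutions
    of the same minimization. A non-SPD system (e.g. a zero outdegree) is
    rejected with the smallest eigenvalue estimate.
    """
    Wm = np.asarray(W.W, dtype=float)
    d = np.asarray(D.d, dtype=float)
    if d.size != Wm.shape[1]:
        raise ValueError("outdegree length does not match pixel count")
    if d.min() <= 0:
        raise ValueError(
            f"system is not positive definite: smallest eigenvalue <= "
            f"{d.min():.3g} (zero-outdegree pixel; apply the epsilon floor)"
        )
    v, p = Wm.shape
    if p <= DIRECT_SOLVE_MAX_P or p <= v:
        A = Wm.T @ Wm
        A[np.diag_indices_from(A)] += d
        factor = _chol_or_raise(A)
        return ProjectionMatrix(W=Wm, d=d, _route="direct", _factor=factor,
                                grid=W.grid)
    K = Wm @ (Wm / d).T
    K[np.diag_indices_from(K)] += 1.0
    factor = _chol_or_raise(K)
    return ProjectionMatrix(W=Wm, d=d, _route="woodbury", _factor=factor,
                            grid=W.grid)


def _chol_or_raise(A: np.ndarray):
    try:
        return cho_factor(A, lower=True)
    except np.linalg.LinAlgError as err:
        smallest = float(np.linalg.eigvalsh(A)[0])
        raise ValueError(
            f"system is not positive definite (smallest eigenvalue "
            f"~ {smallest:.3g})"
        ) from err


@dataclass
class ReconstructedImage:
    """Reconstructed visual field (arbitrary activation units)."""

    x: np.ndarray  # (p,)
    grid: VisualFieldGrid
    pattern_id: str = ""
    denoised: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.x).all():
            raise ValueError("reconstruction contains non-finite values")

    def raster(self) -> np.ndarray:
        return devectorize_image(self.x, self.grid)


def reconstruct(
    P: ProjectionMatrix,
    y: np.ndarray | VoxelPattern,
    pattern_id: str = "",
    denoised: bool = False,
) -> ReconstructedImage:
    """x = W_VF @ y; linear in y."""
    vec = y.values if isinstance(y, VoxelPattern) else np.asarray(y, dtype=float)
    if vec.ndim != 1:
        raise ValueError("reconstruct takes a single pattern")
    x = P.apply(vec)
    grid = P.grid
    if grid is None:
        n = int(round(np.sqrt(x.size)))
        grid = VisualFieldGrid(n_rows=n, n_cols=n)
    if isinstance(y, VoxelPattern) and not pattern_id:
        pattern_id = f"{y.condition}:{y.letter}:run{y.run}:trial{y.trial}"
    return ReconstructedImage(x=x, grid=grid, pattern_id=pattern_id,
                              denoised=denoised)


# -- quality metrics ---------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(a, b).statistic)


def first_level_r(x: ReconstructedImage | np.ndarray, letter: LetterImage) -> float:
    """Pearson r between a reconstruction and the binary letter, over all
    pixels."""
    vec = x.x if isinstance(x, ReconstructedImage) else np.asarray(x).ravel()
    target = letter.pixels.ravel().astype(float)
    if vec.size != target.size:
        raise ValueError("reconstruction and letter are on different grids")
    return _pearson(vec, target)


def pairwise_correlations(images: dict[str, np.ndarray]) -> np.ndarray:
    """C(4,2) = 6 pairwise correlations in canonical letter-pair order."""
    missing = [L for L in LETTERS if L not in images]
    if missing:
        raise ValueError(f"missing letters: {missing}")
    return np.asarray(
        [
            _pearson(np.ravel(images[a]).astype(float),
                     np.ravel(images[b]).astype(float))
            for a, b in combinations(LETTERS, 2)
        ]
    )


def second_level_r(
    recons: dict[str, ReconstructedImage], letters: dict[str, LetterImage]
) -> float:
    """Correlation between the 6 pairwise letter-letter correlations and
    the 6 pairwise reconstruction-reconstruction correlations."""
    rv = pairwise_correlations({L: r.x for L, r in recons.items()})
    lv = pairwise_correlations({L: i.pixels for L, i in letters.items()})
    return _pearson(rv, lv)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform for aggregating correlations."""
    return np.arctanh(r)
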