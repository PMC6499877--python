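"""Letter stimuli and bar-aperture sequences on a calibrated visual-field raster.

Coordinate convention (used throughout the package): pixel *centers*, x
rightward, y upward, fixation at (0, 0), degrees of visual angle as units.
Rasters are stored row-major with row 0 at the top of the visual field, and
``vectorize_image`` flattens in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

LETTERS = ("H", "T", "S", "C")

#: side length of the square guide box the letters are drawn in (degrees)
GUIDE_BOX_DEG = 8.0


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square pixel raster mapped onto degrees of visual angle.

    Parameters
    ----------
    n_rows, n_cols:
        Raster size in pixels (default 150 x 150).
    extent:
        Full width/height of the raster in degrees. The default of 10 deg
        leaves a 1 deg margin around the 8 x 8 deg letter guide box.
    """

    n_rows: int = 150
    n_cols: int = 150
    extent: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows != self.n_cols:
            raise ValueError("grid must be square")
        if self.extent <= 0:
            raise ValueError("extent must be positive (degrees)")

    @property
    def deg_per_px(self) -> float:
        return self.extent / self.n_cols

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinates of pixel centers, each shaped (n_rows, n_cols).

        Pixel centers are symmetric about fixation: column j has
        x = (j - (n_cols-1)/2) * deg_per_px and row i has
        y = ((n_rows-1)/2 - i) * deg_per_px (y axis points upward).
        """
        d = self.deg_per_px
        x = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * d
        y = ((self.n_rows - 1) / 2.0 - np.arange(self.n_rows)) * d
        return np.meshgrid(x, y)

    def pixel_centers_flat(self) -> tuple[np.ndarray, np.ndarray]:
        X, Y = self.pixel_centers()
        return X.ravel(), Y.ravel()


@dataclass(frozen=True)
class LetterImage:
    """Binary raster of one letter glyph inside the guide box."""

    letter: str
    pixels: np.ndarray
    grid: VisualFieldGrid
    stroke_width: float
    box: float = GUIDE_BOX_DEG

    def __post_init__(self) -> None:
        px = self.pixels
        if px.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("pixel raster does not match grid shape")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("letter raster must be binary")
        if px.sum() == 0:
            raise ValueError(f"letter {self.letter!r} rendered no pixels")


# -- glyph geometry ----------------------------------------------------------
#
# Glyphs are unions of axis-aligned bars and annulus sectors filling the
# guide box. 'T' and 'H' are coarse (wide straight strokes), 'S' is the
# finest (two stacked opposing arcs), matching the qualitative
# coarse-to-fine ordering T > H > C > S of reconstruction difficulty.


def _bar(X, Y, x0, x1, y0, y1):
    return (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)


def _annulus_sector(X, Y, cx, cy, r_in, r_out, gap_lo, gap_hi):
    """Annulus around (cx, cy) with the angular interval (gap_lo, gap_hi)
    removed (angles in radians, measured anticlockwise from +x)."""
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    in_ring = (r >= r_in) & (r <= r_out)
    in_gap = (theta > gap_lo) & (theta < gap_hi)
    return in_ring & ~in_gap


def _glyph_mask(letter: str, X, Y, w: float, box: float) -> np.ndarray:
    h = box / 2.0
    if letter == "H":
        return (
            _bar(X, Y, -h, -h + w, -h, h)
            | _bar(X, Y, h - w, h, -h, h)
            | _bar(X, Y, -h, h, -w / 2, w / 2)
        )
    if letter == "T":
        return _bar(X, Y, -h, h, h - w, h) | _bar(X, Y, -w / 2, w / 2, -h, h)
    if letter == "C":
        # open ring, gap facing right (+/- 45 deg around the +x axis)
        return _annulus_sector(X, Y, 0.0, 0.0, h - w, h, -np.pi / 4, np.pi / 4)
    if letter == "S":
        # two stacked opposing arcs: top hook open to the lower right,
        # bottom hook open to the upper left
        top = _annulus_sector(X, Y, 0.0, h / 2, h / 2 - w, h / 2, -np.pi / 2, 0.0)
        bot = _annulus_sector(X, Y, 0.0, -h / 2, h / 2 - w, h / 2, np.pi / 2, np.pi)
        return top | bot
    raise ValueError(f"unknown letter id {letter!r}; expected one of {LETTERS}")


def render_letter(
    letter: str,
    grid: VisualFieldGrid | None = None,
    stroke_width: float = 1.2,
    box: float = GUIDE_BOX_DEG,
) -> LetterImage:
    """Rasterize one of the four letter glyphs (H, T, S, C).

    A pixel is on iff its center lies inside the glyph's stroke geometry;
    the result is deterministic for fixed inputs.
    """
    if grid is None:
        grid = VisualFieldGrid()
    if letter not in LETTERS:
        raise ValueError(f"unknown letter id {letter!r}; expected one of {LETTERS}")
    if not 0 < stroke_width < box:
        raise ValueError(
            f"stroke_width must lie in (0, {box}); got {stroke_width}"
        )
    if box > grid.extent:
        raise ValueError("guide box does not fit inside the grid extent")
    X, Y = grid.pixel_centers()
    mask = _glyph_mask(letter, X, Y, stroke_width, box)
    return LetterImage(
        letter=letter,
        pixels=mask.astype(np.uint8),
        grid=grid,
        stroke_width=stroke_width,
        box=box,
    )


def render_letter_set(
    grid: VisualFieldGrid | None = None, stroke_width: float = 1.2
) -> dict[str, LetterImage]:
    """All four letters on a common grid, keyed by letter id."""
    if grid is None:
        grid = VisualFieldGrid()
    return {L: render_letter(L, grid, stroke_width) for L in LETTERS}


# -- bar apertures -----------------------------------------------------------


@dataclass
class ApertureSequence:
    """Randomized bar-aperture mapping sequence.

    One binary frame per functional volume: 4 orientations x 6 repetitions
    x 12 bar steps = 288 frames at one 3 s step per volume. Within each
    orientation-repetition block the 12 step positions are a random
    permutation (fixed by ``seed``).
    """

    frames: np.ndarray  # (n_frames, n_rows, n_cols) uint8
    grid: VisualFieldGrid
    orientations_deg: tuple[float, ...]
    step_width: float
    steps_per_orientation: int
    repetitions: int
    step_duration: float
    seed: int
    step_order: np.ndarray = field(repr=False, default=None)  # (n_frames,) int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_matrix(self) -> np.ndarray:
        """Frames vectorized row-major into an (n_frames, p) float array."""
        return self.frames.reshape(self.n_frames, -1).astype(float)


def render_bar_apertures(
    grid: VisualFieldGrid | None = None,
    seed: int = 0,
    step_width: float = 1.33,
    steps_per_orientation: int = 12,
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    repetitions: int = 6,
    step_duration: float = 3.0,
) -> ApertureSequence:
    """Bar-aperture frames sweeping the full raster in discrete steps.

    For each orientation the 12 step positions tile the raster's projection
    onto the bar normal, so the union of steps covers every pixel (at the
    default sizes consecutive 1.33 deg bands overlap). The step order is
    randomized independently within each orientation repetition.
    """
    if grid is None:
        grid = VisualFieldGrid()
    rng = np.random.default_rng(seed)
    X, Y = grid.pixel_centers()
    frames, order = [], []
    for ang in orientations_deg:
        a = np.deg2rad(ang)
        # bar runs along (cos a, sin a); pixel projection onto the normal
        proj = -X * np.sin(a) + Y * np.cos(a)
        lo, hi = proj.min(), proj.max()
        pitch = (hi - lo) / steps_per_orientation
        centers = lo + (np.arange(steps_per_orientation) + 0.5) * pitch
        half = max(step_width, pitch) / 2.0  # guarantee coverage
        for _ in range(repetitions):
            perm = rng.permutation(steps_per_orientation)
            for idx in perm:
                frames.append(np.abs(proj - centers[idx]) <= half)
                order.append(idx)
    return ApertureSequence(
        frames=np.asarray(frames, dtype=np.uint8),
        grid=grid,
        orientations_deg=tuple(orientations_deg),
        step_width=step_width,
        steps_per_orientation=steps_per_orientation,
        repetitions=repetitions,
        step_duration=step_duration,
        seed=seed,
        step_order=np.asarray(order),
    )


# -- vectorization -----------------------------------------------------------


def vectorize_image(img: np.ndarray | LetterImage) -> np.ndarray:
    """Flatten a raster to a length n_rows*n_cols vector (row-major)."""
    raster = img.pixels if isinstance(img, LetterImage) else np.asarray(img)
    if raster.ndim != 2:
        raise ValueError("expected a 2-D raster")
    return raster.reshape(-1)


def devectorize_image(vec: np.ndarray, grid: VisualFieldGrid) -> np.ndarray:
    """Inverse of :func:`vectorize_image` on the given grid."""
    vec = np.asarray(vec)
    if vec.size != grid.n_pixels:
        raise ValueError(
            f"vector length {vec.size} does not match grid ({grid.n_pixels} px)"
        )
    return vec.reshape(grid.n_rows, grid.n_cols)


# -- export ------------------------------------------------------------------


def save_raster_png(raster: np.ndarray, path, metadata: dict | None = None) -> None:
    """Write a raster as an 8-bit grayscale PNG (min-max scaled), with an
    optional JSON sidecar holding provenance metadata."""
    from PIL import Image

    arr = np.asarray(raster, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)
    if metadata is not None:
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=2)
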