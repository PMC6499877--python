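"""Synthetic retinotopic voxel populations and BOLD-like session data.

This generator is first-class: it defines the study conditions under which
the analysis is exercised. A population of voxels with isotropic Gaussian
pRFs (width proportional to eccentricity) responds to bar-aperture mapping
runs, letter perception runs, and imagery runs. Imagery is modeled as an
attenuated, noisier copy of the perceptual drive: drive_imagery =
imagery_gain * drive_perception, with additive white Gaussian noise of
``imagery_noise_sd`` z-units (defaults: gain 0.5, noise 2x perceptual),
reproducing imagery reconstructions that are topographically faithful but
of inferior quality relative to perception.

What the generator does NOT emulate: physiological/structured noise,
temporal autocorrelation, motion, scanner drift beyond an optional linear
term, or between-subject vividness differences other than via the
gain/noise settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemo import HRFSpec, convolve_hrf
from .prf import PRFParams, SIGMA_FLOOR, response_matrix
from .stimuli import (
    ApertureSequence,
    LETTERS,
    LetterImage,
    VisualFieldGrid,
    vectorize_image,
)


@dataclass
class VoxelPopulation:
    """Ground-truth voxel population for one ROI."""

    prfs: list[PRFParams]
    roi_label: str = "V1"
    noise_sd: float = 1.0
    imagery_gain: float = 0.5
    imagery_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.imagery_gain <= 1.0:
            raise ValueError("imagery_gain must lie in [0, 1]")
        if self.noise_sd < 0 or self.imagery_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return len(self.prfs)

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        x0 = np.asarray([p.x0 for p in self.prfs])
        y0 = np.asarray([p.y0 for p in self.prfs])
        sg = np.asarray([p.sigma for p in self.prfs])
        sl = np.asarray([np.nan if p.slope is None else p.slope for p in self.prfs])
        return x0, y0, sg, sl


def combine_populations(pops: list[VoxelPopulation], roi_label: str) -> VoxelPopulation:
    """Union of several ROIs' voxels (e.g. the combined V1V2V3 ROI)."""
    first = pops[0]
    return VoxelPopulation(
        prfs=[p for pop in pops for p in pop.prfs],
        roi_label=roi_label,
        noise_sd=first.noise_sd,
        imagery_gain=first.imagery_gain,
        imagery_noise_sd=first.imagery_noise_sd,
    )


def sample_population(
    n: int,
    ecc_max: float,
    slope: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    roi_label: str = "V1",
    sigma_floor: float = SIGMA_FLOOR,
    noise_sd: float = 1.0,
    imagery_gain: float = 0.5,
    imagery_noise_sd: float = 2.0,
) -> VoxelPopulation:
    """Sample a voxel population with uniform pRF coverage of the field.

    Centers are uniform over the disk of radius ``ecc_max``; widths follow
    sigma = max(slope * eccentricity, sigma_floor) + Gaussian jitter
    (clipped below at the floor). Reproducible under ``seed``.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if not 0.1 <= slope <= 1.0:
        raise ValueError("slope must lie in [0.1, 1.0]")
    rng = np.random.default_rng(seed)
    # uniform over the disk via sqrt of the radial CDF
    ecc = ecc_max * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0.0, 2 * np.pi, size=n)
    sigma = np.maximum(slope * ecc, sigma_floor)
    if jitter_sd > 0:
        sigma = np.maximum(sigma + rng.normal(0.0, jitter_sd, size=n), sigma_floor)
    prfs = [
        PRFParams(
            x0=float(e * np.cos(a)),
            y0=float(e * np.sin(a)),
            sigma=float(s),
            slope=slope,
        )
        for e, a, s in zip(ecc, ang, sigma)
    ]
    return VoxelPopulation(
        prfs=prfs,
        roi_label=roi_label,
        noise_sd=noise_sd,
        imagery_gain=imagery_gain,
        imagery_noise_sd=imagery_noise_sd,
    )


# -- session design ----------------------------------------------------------


@dataclass
class RunDesign:
    """One run's trial bookkeeping (volumes, TR-locked)."""

    run_type: str  # mapping | perception | imagery
    n_volumes: int
    onsets: np.ndarray  # trial onset volume indices
    labels: list[str]  # letter per trial (empty for mapping)

    def __post_init__(self) -> None:
        if self.run_type not in ("mapping", "perception", "imagery"):
            raise ValueError(f"unknown run type {self.run_type!r}")
        if len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must align")
        if len(self.onsets) > 1 and not (np.diff(self.onsets) > 0).all():
            raise ValueError("trial onsets must be strictly increasing")


@dataclass
class SessionDesign:
    """Trial/run layout of one scanning session.

    Defaults mirror the study design: TR 3 s; 4 imagery runs of 32 normal
    trials (8 per letter, catch trials excluded); one perception run of
    8 trials per letter; 6 s stimulation/imagery phases; rests alternating
    pseudo-randomly between 9 and 12 s.
    """

    tr: float = 3.0
    stim_volumes: int = 2  # 6 s at TR 3 s
    rest_volume_choices: tuple[int, ...] = (3, 4)  # 9 s or 12 s
    lead_volumes: int = 2
    trail_volumes: int = 4
    n_imagery_runs: int = 4
    imagery_trials_per_letter: int = 8
    perception_trials_per_letter: int = 8
    runs: list[RunDesign] = field(default_factory=list)

    def imagery_runs(self) -> list[RunDesign]:
        return [r for r in self.runs if r.run_type == "imagery"]

    def perception_runs(self) -> list[RunDesign]:
        return [r for r in self.runs if r.run_type == "perception"]

    def validate(self) -> None:
        for r in self.imagery_runs():
            counts = {L: r.labels.count(L) for L in LETTERS}
            if any(c != self.imagery_trials_per_letter for c in counts.values()):
                raise ValueError(
                    f"imagery run letter counts {counts} violate the design"
                )
        for r in self.runs:
            if len(r.onsets) and r.onsets[-1] + self.stim_volumes > r.n_volumes:
                raise ValueError("trial extends past end of run")


def make_session_design(seed: int = 0, **overrides) -> SessionDesign:
    """Build a randomized session design (trial orders and rest durations
    drawn from ``seed``)."""
    design = SessionDesign(**overrides)
    rng = np.random.default_rng(seed)

    def _trial_run(run_type: str, trials_per_letter: int) -> RunDesign:
        labels = [L for L in LETTERS for _ in range(trials_per_letter)]
        order = rng.permutation(len(labels))
        labels = [labels[i] for i in order]
        onsets, t = [], design.lead_volumes
        for _ in labels:
            onsets.append(t)
            t += design.stim_volumes + int(rng.choice(design.rest_volume_choices))
        return RunDesign(
            run_type=run_type,
            n_volumes=t + design.trail_volumes,
            onsets=np.asarray(onsets),
            labels=labels,
        )

    design.runs.append(_trial_run("perception", design.perception_trials_per_letter))
    for _ in range(design.n_imagery_runs):
        design.runs.append(_trial_run("imagery", design.imagery_trials_per_letter))
    design.validate()
    return design


# -- simulation --------------------------------------------------------------


def _znorm_time(ts: np.ndarray) -> np.ndarray:
    """Per-voxel z-normalization over time; constant rows stay at zero."""
    mu = ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1, keepdims=True)
    out = ts - mu
    np.divide(out, sd, out=out, where=sd > 0)
    return out


def simulate_run(
    pop: VoxelPopulation,
    frames: ApertureSequence,
    hrf: HRFSpec,
    noise_sd: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a (v, T) BOLD-like run from per-volume stimulus frames.

    Neural drive per voxel and volume is the pixel sum of the (unit-sum)
    Gaussian pRF times the frame, convolved with the HRF; white Gaussian
    noise is added and each voxel's series is z-normalized.
    """
    if noise_sd is None:
        noise_sd = pop.noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    W = response_matrix(pop.prfs, frames.grid)
    drive = W @ frames.frame_matrix().T  # (v, T)
    ts = convolve_hrf(drive, hrf)
    if noise_sd > 0:
        # noise_sd is expressed relative to the peak evoked amplitude, so
        # populations with different pRF sizes see comparable SNR
        ref = np.abs(ts).max()
        rng = np.random.default_rng(seed)
        ts = ts + rng.normal(0.0, noise_sd * (ref if ref > 0 else 1.0),
                             size=ts.shape)
    return _znorm_time(ts)


def _trial_drive_series(
    run: RunDesign,
    letter_drive: dict[str, np.ndarray],
    stim_volumes: int,
    gain: float,
) -> np.ndarray:
    v = next(iter(letter_drive.values())).size
    drive = np.zeros((v, run.n_volumes))
    for onset, label in zip(run.onsets, run.labels):
        drive[:, onset : onset + stim_volumes] += gain * letter_drive[label][:, None]
    return drive


@dataclass
class SessionData:
    """Simulated session: per-run time series plus ground-truth metadata."""

    pop: VoxelPopulation
    design: SessionDesign
    grid: VisualFieldGrid
    hrf: HRFSpec
    mapping: ApertureSequence | None
    mapping_ts: np.ndarray | None
    run_ts: list[np.ndarray]  # aligned with design.runs
    seed: int


def generate_session(
    pop: VoxelPopulation,
    design: SessionDesign,
    letters: dict[str, LetterImage],
    hrf: HRFSpec,
    seed: int = 0,
    mapping: ApertureSequence | None = None,
) -> SessionData:
    """Simulate mapping, perception, and imagery runs for one population.

    Perception trials drive each voxel with its pRF-letter overlap; imagery
    trials use ``imagery_gain`` times that drive and ``imagery_noise_sd``
    noise. All runs share the population; ground truth is kept in the
    returned metadata.
    """
    missing = [L for L in LETTERS if L not in letters]
    if missing:
        raise ValueError(f"missing letter rasters: {missing}")
    design.validate()
    grid = letters[LETTERS[0]].grid
    W = response_matrix(pop.prfs, grid)
    letter_drive = {L: W @ vectorize_image(letters[L]).astype(float) for L in LETTERS}

    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(len(design.runs) + 1)
    rng_map_seed = run_seeds[-1]

    # noise reference: peak amplitude of a full-gain (perception) trial
    # response, so imagery gain < 1 is a genuine SNR reduction
    kernel = hrf.kernel()
    boxcar_peak = np.convolve(np.ones(design.stim_volumes), kernel).max()
    ref = max(d.max() for d in letter_drive.values()) * boxcar_peak
    if ref <= 0:
        ref = 1.0

    run_ts = []
    for run, rs in zip(design.runs, run_seeds):
        gain = pop.imagery_gain if run.run_type == "imagery" else 1.0
        sd = pop.imagery_noise_sd if run.run_type == "imagery" else pop.noise_sd
        drive = _trial_drive_series(run, letter_drive, design.stim_volumes, gain)
        ts = convolve_hrf(drive, hrf)
        if sd > 0:
            rng = np.random.default_rng(rs)
            ts = ts + rng.normal(0.0, sd * ref, size=ts.shape)
        run_ts.append(_znorm_time(ts))

    mapping_ts = None
    if mapping is not None:
        mapping_ts = simulate_run(
            pop, mapping, hrf, noise_sd=pop.noise_sd,
            seed=rng_map_seed.generate_state(1)[0] % (2**31),
        )
    return SessionData(
        pop=pop,
        design=design,
        grid=grid,
        hrf=hrf,
        mapping=mapping,
        mapping_ts=mapping_ts,
        run_ts=run_ts,
        seed=seed,
    )
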