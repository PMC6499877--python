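"""End-to-end orchestration: simulate -> fit -> extract -> encode ->
reconstruct -> denoise -> classify, per simulated subject and ROI.

The three early visual areas are emulated as one combined voxel population
(pRF size slopes increasing from V1 to V3) recorded in a single session;
per-ROI analyses slice that population, and the combined V1V2V3 ROI is the
union of the three. Every stochastic stage draws its seed from one master
seed via a SeedSequence spawn, so a fixed master seed reproduces every
artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .autoencoder import (
    autoencoder_config,
    classifier_config,
    denoise,
    loro_cross_validate,
    permutation_test,
    train_autoencoder,
)
from .encoding import contrast_test, fit_letter_regression, predicted_design
from .hemo import HRFSpec
from .patterns import PatternSet, average_letter_patterns, extract_session_patterns
from .prf import build_encoding_matrix, build_search_grid, fit_prf_many
from .reconstruct import (
    compute_outdegree,
    compute_projection,
    first_level_r,
    reconstruct,
    second_level_r,
)
from .stimuli import (
    LETTERS,
    VisualFieldGrid,
    render_bar_apertures,
    render_letter_set,
    save_raster_png,
)
from .synth import (
    combine_populations,
    generate_session,
    make_session_design,
    sample_population,
)


@dataclass(frozen=True)
class ROISettings:
    """Per-ROI population settings (pRF slope grows from V1 to V3)."""

    n_voxels: int
    slope: float
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Schema-validated pipeline configuration.

    ``from_dict`` rejects unknown keys; ``to_json`` serializes the full
    config into every results directory for provenance.
    """

    grid_n: int = 150
    grid_extent: float = 10.0
    fit_grid_n: int = 64  # stimulus raster used for pRF fitting
    stroke_width: float = 1.2
    rois: tuple[tuple[str, ROISettings], ...] = (
        ("V1", ROISettings(n_voxels=700, slope=0.15)),
        ("V2", ROISettings(n_voxels=700, slope=0.25)),
        ("V3", ROISettings(n_voxels=600, slope=0.35)),
    )
    noise_sd: float = 1.0
    imagery_gain: float = 0.5
    imagery_noise_sd: float = 2.0
    n_subjects: int = 6
    n_imagery_runs: int = 4
    search_n_angles: int = 100
    search_n_ecc: int = 100
    search_decay: float = 3.0
    fit_threshold: float = 0.2
    ae_iterations: int = 2000
    clf_iterations: int = 250
    n_permutations: int = 1000
    master_seed: int = 0
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_imagery_runs < 1:
            raise ValueError("need at least one subject and one imagery run")
        if not 0 <= self.fit_threshold < 1:
            raise ValueError("fit_threshold must lie in [0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "rois" in data:
            data["rois"] = tuple(
                (name, ROISettings(**settings)) for name, settings in data["rois"]
            )
        return cls(**data)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["rois"] = [[name, dataclasses.asdict(s)] for name, s in self.rois]
        return json.dumps(d, indent=2)

    def roi_names(self) -> list[str]:
        return [name for name, _ in self.rois]


@dataclass
class SubjectResult:
    """Per-subject metric tables and intermediate objects."""

    subject: int
    metrics: pd.DataFrame  # first/second-level r by ROI, letter, condition
    accuracy: pd.DataFrame  # LORO + permutation results by ROI
    betas: dict  # roi -> (4, 4) betas, imagined letter x physical letter
    n_selected: dict  # roi -> selected voxel count
    reconstructions: dict = field(default_factory=dict, repr=False)


@dataclass
class RunReport:
    config: PipelineConfig
    subjects: list[SubjectResult]
    contrasts: pd.DataFrame  # group-level contrast tests (letter x ROI)
    output_dir: Path


def _subject_seed(master_seed: int, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(subject,))


def run_subject(
    config: PipelineConfig,
    subject: int,
    save_to: Path | None = None,
    use_true_prfs: bool = False,
) -> SubjectResult:
    """Full pipeline for one simulated subject.

    ``use_true_prfs`` skips the grid-search stage and builds the encoding
    matrix from the generating parameters (a noise-free upper bound used
    by fast checks; the default fits the pRFs from the mapping run).
    """
    ss = _subject_seed(config.master_seed, subject)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    grid = VisualFieldGrid(config.grid_n, config.grid_n, config.grid_extent)
    fit_grid = VisualFieldGrid(config.fit_grid_n, config.fit_grid_n,
                               config.grid_extent)
    letters = render_letter_set(grid, config.stroke_width)
    ecc_max = config.grid_extent / np.sqrt(2.0)  # pRFs out to the corners

    pops = [
        sample_population(
            s.n_voxels, ecc_max, s.slope, s.jitter_sd, seed=seeds[0] + i,
            roi_label=name, noise_sd=config.noise_sd,
            imagery_gain=config.imagery_gain,
            imagery_noise_sd=config.imagery_noise_sd,
        )
        for i, (name, s) in enumerate(config.rois)
    ]
    pop_all = combine_populations(pops, "V1V2V3")
    roi_slices = {}
    start = 0
    for (name, _), pop in zip(config.rois, pops):
        roi_slices[name] = np.arange(start, start + pop.n_voxels)
        start += pop.n_voxels
    roi_slices["V1V2V3"] = np.arange(start)

    design = make_session_design(
        seed=seeds[1], n_imagery_runs=config.n_imagery_runs
    )
    mapping = render_bar_apertures(fit_grid, seed=seeds[2])
    hrf = HRFSpec()
    session = generate_session(pop_all, design, letters, hrf, seed=seeds[3],
                               mapping=mapping)

    if use_true_prfs:
        fitted_prfs = pop_all.prfs
        scores = np.ones(pop_all.n_voxels)
    else:
        sgrid = build_search_grid(
            ecc_max, decay=config.search_decay,
            n_angles=config.search_n_angles, n_ecc=config.search_n_ecc,
        )
        fits = fit_prf_many(session.mapping_ts, mapping, hrf, sgrid)
        fitted_prfs = [f.best for f in fits]
        scores = np.asarray([f.score if f.valid else -np.inf for f in fits])

    metrics_rows, acc_rows, betas_all, n_selected = [], [], {}, {}
    recons_store = {}
    ae_cfg = autoencoder_config(seed=seeds[4])
    ae_cfg = dataclasses.replace(ae_cfg, iterations=config.ae_iterations)
    clf_cfg = classifier_config(seed=seeds[5])
    clf_cfg = dataclasses.replace(clf_cfg, iterations=config.clf_iterations)

    for roi in config.roi_names() + ["V1V2V3"]:
        sel_local = np.where(scores[roi_slices[roi]] >= config.fit_threshold)[0]
        if sel_local.size == 0:
            raise ValueError(f"no voxel passed the fit threshold in {roi}")
        voxels = roi_slices[roi][sel_local]
        n_selected[roi] = voxels.size
        W = build_encoding_matrix([fitted_prfs[i] for i in voxels], grid,
                                  voxel_indices=voxels)
        D = compute_outdegree(W)
        P = compute_projection(W, D)

        pset = _roi_patterns(session, voxels)
        perc_avg = average_letter_patterns(pset, "perception")
        imag_avg = average_letter_patterns(pset, "imagery")

        # encoding betas: observed average imagery pattern per imagined
        # letter, regressed on the four predicted patterns
        pred = predicted_design(W, letters)
        betas_all[roi] = np.vstack(
            [fit_letter_regression(imag_avg[L], pred) for L in LETTERS]
        )

        ae = train_autoencoder(
            np.vstack([perc_avg[L].values for L in LETTERS]), ae_cfg
        )

        recons_roi = {}
        for cond, avg in (("perception", perc_avg), ("imagery", imag_avg)):
            recs = {}
            for L in LETTERS:
                rec = reconstruct(P, avg[L])
                recs[L] = rec
                metrics_rows.append(dict(
                    subject=subject, roi=roi, letter=L, condition=cond,
                    denoised=False, first_level_r=first_level_r(rec, letters[L]),
                ))
            for row, L in zip(metrics_rows[-4:], LETTERS):
                row["second_level_r"] = np.nan
            slr = second_level_r(recs, letters)
            for row in metrics_rows[-4:]:
                row["second_level_r"] = slr
            recons_roi[cond] = recs
            if cond == "imagery":
                den = {}
                for L in LETTERS:
                    rec = reconstruct(P, denoise(ae, imag_avg[L].values),
                                      pattern_id=f"imagery:{L}", denoised=True)
                    den[L] = rec
                    metrics_rows.append(dict(
                        subject=subject, roi=roi, letter=L, condition=cond,
                        denoised=True,
                        first_level_r=first_level_r(rec, letters[L]),
                        second_level_r=np.nan,
                    ))
                slr = second_level_r(den, letters)
                for row in metrics_rows[-4:]:
                    row["second_level_r"] = slr
                recons_roi["imagery_denoised"] = den
        recons_store[roi] = recons_roi

        loro = loro_cross_validate(pset, ae, clf_cfg)
        perm = permutation_test(
            pset, ae, clf_cfg, n_permutations=config.n_permutations,
            seed=seeds[5] + 17, observed=loro,
        )
        acc_rows.append(dict(
            subject=subject, roi=roi, n_voxels=voxels.size,
            mean_accuracy=loro.mean_accuracy,
            null_mean=perm.null_mean, null_p95=perm.threshold,
            significant=perm.significant,
        ))

    result = SubjectResult(
        subject=subject,
        metrics=pd.DataFrame(metrics_rows),
        accuracy=pd.DataFrame(acc_rows),
        betas=betas_all,
        n_selected=n_selected,
        reconstructions=recons_store,
    )
    if save_to is not None:
        _save_subject(result, save_to)
    return result


def _roi_patterns(session, voxels: np.ndarray) -> PatternSet:
    """Extract patterns restricted to an ROI's voxels (spatial z-scoring is
    ROI-specific, so the slice happens before extraction)."""
    sliced = dataclasses.replace(
        session, run_ts=[ts[voxels] for ts in session.run_ts]
    )
    return extract_session_patterns(sliced)


def _save_subject(result: SubjectResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / f"metrics_s{result.subject:02d}.csv",
                          index=False)
    result.accuracy.to_csv(outdir / f"accuracy_s{result.subject:02d}.csv",
                           index=False)
    for roi, conds in result.reconstructions.items():
        for cond, recs in conds.items():
            for L, rec in recs.items():
                save_raster_png(
                    rec.raster(),
                    outdir / f"recon_s{result.subject:02d}_{roi}_{cond}_{L}.png",
                )


def run_pipeline(config: PipelineConfig, use_true_prfs: bool = False) -> RunReport:
    """Run all subjects and the group-level contrast analysis.

    Writes metric CSVs, reconstruction PNGs, the contrast table, and the
    config echo under ``config.output_dir``; rerunning with the same
    master seed reproduces identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    subjects = [
        run_subject(config, s, save_to=outdir, use_true_prfs=use_true_prfs)
        for s in range(config.n_subjects)
    ]
    rows = []
    for roi in config.roi_names():  # single-area family, as in the 12-test design
        for li, L in enumerate(LETTERS):
            betas = np.vstack([s.betas[roi][li] for s in subjects])
            if len(subjects) >= 3:
                res = contrast_test(betas, L, roi=roi)
                rows.append(dict(
                    roi=roi, letter=L, t=res.t, p=res.p,
                    corrected_alpha=res.corrected_alpha,
                    significant=res.significant,
                ))
            else:
                rows.append(dict(roi=roi, letter=L, t=np.nan, p=np.nan,
                                 corrected_alpha=np.nan, significant=False))
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    pd.concat([s.accuracy for s in subjects]).to_csv(
        outdir / "accuracy.csv", index=False
    )
    pd.concat([s.metrics for s in subjects]).to_csv(
        outdir / "metrics.csv", index=False
    )
    return RunReport(config=config, subjects=subjects, contrasts=contrasts,
                     output_dir=outdir)


# -- fixtures ----------------------------------------------------------------

FIXTURE_SIZES = {
    "tiny": dict(
        grid_n=64, fit_grid_n=48, n_subjects=1,
        rois=(("V1", ROISettings(n_voxels=80, slope=0.15)),
              ("V2", ROISettings(n_voxels=70, slope=0.25)),
              ("V3", ROISettings(n_voxels=50, slope=0.35))),
        search_n_angles=24, search_n_ecc=24,
        n_permutations=200,
    ),
    "default": dict(
        grid_n=150, fit_grid_n=64, n_subjects=6,
        rois=(("V1", ROISettings(n_voxels=700, slope=0.15)),
              ("V2", ROISettings(n_voxels=700, slope=0.25)),
              ("V3", ROISettings(n_voxels=600, slope=0.35))),
    ),
}


def fixture_config(size: str = "tiny", master_seed: int = 0,
                   **overrides) -> PipelineConfig:
    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    kwargs = dict(FIXTURE_SIZES[size])
    kwargs.update(overrides, master_seed=master_seed)
    return PipelineConfig(**kwargs)


def make_fixture(size: str = "tiny", master_seed: int = 0, save_to=None):
    """Generate a packaged synthetic dataset (sessions for all subjects).

    Returns ``(sessions, checksum)``; the checksum is stable under a fixed
    master seed, so regeneration can be verified.
    """
    config = fixture_config(size, master_seed)
    grid = VisualFieldGrid(config.grid_n, config.grid_n, config.grid_extent)
    fit_grid = VisualFieldGrid(config.fit_grid_n, config.fit_grid_n,
                               config.grid_extent)
    letters = render_letter_set(grid, config.stroke_width)
    hrf = HRFSpec()
    ecc_max = config.grid_extent / np.sqrt(2.0)
    sessions = []
    arrays = {}
    for s in range(config.n_subjects):
        ss = _subject_seed(master_seed, s)
        seeds = [int(x.generate_state(1)[0] % (2**31)) for x in ss.spawn(6)]
        pops = [
            sample_population(
                st.n_voxels, ecc_max, st.slope, st.jitter_sd,
                seed=seeds[0] + i, roi_label=name, noise_sd=config.noise_sd,
                imagery_gain=config.imagery_gain,
                imagery_noise_sd=config.imagery_noise_sd,
            )
            for i, (name, st) in enumerate(config.rois)
        ]
        pop = combine_populations(pops, "V1V2V3")
        design = make_session_design(seed=seeds[1])
        mapping = render_bar_apertures(fit_grid, seed=seeds[2])
        session = generate_session(pop, design, letters, hrf, seed=seeds[3],
                                   mapping=mapping)
        sessions.append(session)
        for i, ts in enumerate(session.run_ts):
            arrays[f"s{s}_run{i}"] = ts
        arrays[f"s{s}_mapping"] = session.mapping_ts
        if save_to is not None:
            pio.save_session_h5(
                Path(save_to) / f"subject{s:02d}.h5", session,
                fixture_meta=dict(size=size, master_seed=master_seed),
            )
    return sessions, pio.dataset_checksum(arrays)
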