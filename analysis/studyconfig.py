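"""Shared desk-scale study configuration for the numbered analysis scripts.

Six simulated subjects with V1/V2/V3 populations (pRF size slope growing
across areas), the full session design (one perception run, four imagery
runs of 32 trials), and reduced raster/search-grid sizes so each script
runs in well under a minute. All scripts derive every input
deterministically from one master seed, so they can be run independently
and in any order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import prfdecode as pfd
import prfdecode.pipeline as pl

RESULTS_DIR = str(Path(__file__).resolve().parents[1] / "results" / "analysis")

CONFIG = pl.PipelineConfig(
    grid_n=100,
    fit_grid_n=40,
    rois=(
        ("V1", pl.ROISettings(n_voxels=150, slope=0.15)),
        ("V2", pl.ROISettings(n_voxels=120, slope=0.25)),
        ("V3", pl.ROISettings(n_voxels=100, slope=0.35)),
    ),
    n_subjects=6,
    search_n_angles=40,
    search_n_ecc=40,
    fit_threshold=0.2,
    n_permutations=300,
    master_seed=0,
    output_dir=RESULTS_DIR,
)


def subject_inputs(subject: int, config: pl.PipelineConfig = CONFIG):
    """Deterministically rebuild one subject's simulated session and the
    objects shared across analysis stages."""
    ss = pl._subject_seed(config.master_seed, subject)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    grid = pfd.VisualFieldGrid(config.grid_n, config.grid_n, config.grid_extent)
    fit_grid = pfd.VisualFieldGrid(config.fit_grid_n, config.fit_grid_n,
                                   config.grid_extent)
    letters = pfd.render_letter_set(grid, config.stroke_width)
    ecc_max = config.grid_extent / np.sqrt(2.0)
    pops = [
        pfd.sample_population(
            st.n_voxels, ecc_max, st.slope, st.jitter_sd, seed=seeds[0] + i,
            roi_label=name, noise_sd=config.noise_sd,
            imagery_gain=config.imagery_gain,
            imagery_noise_sd=config.imagery_noise_sd,
        )
        for i, (name, st) in enumerate(config.rois)
    ]
    pop_all = pfd.combine_populations(pops, "V1V2V3")
    roi_slices, start = {}, 0
    for (name, _), pop in zip(config.rois, pops):
        roi_slices[name] = np.arange(start, start + pop.n_voxels)
        start += pop.n_voxels
    roi_slices["V1V2V3"] = np.arange(start)
    design = pfd.make_session_design(seed=seeds[1],
                                     n_imagery_runs=config.n_imagery_runs)
    mapping = pfd.render_bar_apertures(fit_grid, seed=seeds[2])
    hrf = pfd.HRFSpec()
    session = pfd.generate_session(pop_all, design, letters, hrf,
                                   seed=seeds[3], mapping=mapping)
    return dict(
        seeds=seeds, grid=grid, fit_grid=fit_grid, letters=letters,
        pops=pops, pop_all=pop_all, roi_slices=roi_slices, design=design,
        mapping=mapping, hrf=hrf, session=session, config=config,
    )
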