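#!/usr/bin/env python
"""Fit population receptive fields by grid search on the mapping runs.

For each subject, every voxel's bar-mapping time course is fit over the
polar search grid crossed with ten sigma-eccentricity slopes; fits are
written to CSV and compared against the generating ground truth.
"""

import numpy as np
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from studyconfig import CONFIG, RESULTS_DIR, subject_inputs

import prfdecode as pfd
from prfdecode.io import save_fits_csv


def main() -> None:
    outdir = Path(RESULTS_DIR)
    outdir.mkdir(parents=True, exist_ok=True)
    sgrid = pfd.build_search_grid(
        CONFIG.grid_extent / np.sqrt(2), decay=CONFIG.search_decay,
        n_angles=CONFIG.search_n_angles, n_ecc=CONFIG.search_n_ecc,
    )
    for s in range(CONFIG.n_subjects):
        inputs = subject_inputs(s)
        fits = pfd.fit_prf_many(inputs["session"].mapping_ts,
                                inputs["mapping"], inputs["hrf"], sgrid)
        save_fits_csv(outdir / f"prf_fits_s{s:02d}.csv", fits)
        selected = pfd.select_voxels(fits, CONFIG.fit_threshold)
        x0, y0, _, _ = inputs["pop_all"].param_arrays()
        err = np.hypot(
            np.asarray([f.best.x0 for f in fits]) - x0,
            np.asarray([f.best.y0 for f in fits]) - y0,
        )
        print(
            f"subject {s}: {len(selected)}/{len(fits)} voxels pass "
            f"score >= {CONFIG.fit_threshold}; median location error "
            f"{np.median(err[selected]):.2f} deg on the noisy mapping run"
        )
    print(f"fits written to {outdir}/prf_fits_s*.csv")


if __name__ == "__main__":
    main()
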