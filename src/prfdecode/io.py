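"""Array-container (HDF5) and tabular export helpers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .patterns import PatternSet
from .prf import PRFFit


def save_session_h5(path, session, fixture_meta: dict | None = None) -> None:
    """Store a simulated session's time series and design as HDF5 + JSON
    attributes (ground truth included for closed-loop checks)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x0, y0, sg, sl = session.pop.param_arrays()
    with h5py.File(path, "w") as f:
        g = f.create_group("population")
        g.create_dataset("x0", data=x0)
        g.create_dataset("y0", data=y0)
        g.create_dataset("sigma", data=sg)
        g.create_dataset("slope", data=sl)
        g.attrs["roi_label"] = session.pop.roi_label
        g.attrs["noise_sd"] = session.pop.noise_sd
        g.attrs["imagery_gain"] = session.pop.imagery_gain
        g.attrs["imagery_noise_sd"] = session.pop.imagery_noise_sd
        runs = f.create_group("runs")
        for i, (ts, run) in enumerate(zip(session.run_ts, session.design.runs)):
            rg = runs.create_group(f"run{i:02d}")
            rg.create_dataset("ts", data=ts)
            rg.create_dataset("onsets", data=run.onsets)
            rg.attrs["run_type"] = run.run_type
            rg.attrs["labels"] = json.dumps(run.labels)
        if session.mapping_ts is not None:
            f.create_dataset("mapping_ts", data=session.mapping_ts)
        f.attrs["seed"] = session.seed
        f.attrs["tr"] = session.design.tr
        f.attrs["grid_n"] = session.grid.n_rows
        f.attrs["grid_extent"] = session.grid.extent
        if fixture_meta:
            f.attrs["fixture_meta"] = json.dumps(fixture_meta)


def save_fits_csv(path, fits: list[PRFFit]) -> None:
    """Per-voxel fitted pRF parameters and scores."""
    rows = [
        dict(voxel=f.voxel, x0=f.best.x0, y0=f.best.y0, sigma=f.best.sigma,
             slope=f.best.slope, score=f.score, valid=f.valid)
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_patterns_h5(path, pset: PatternSet) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=pset.values)
        f.attrs["manifest"] = pset.manifest.to_json(orient="records")


def load_patterns_h5(path) -> PatternSet:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        manifest = pd.read_json(f.attrs["manifest"], orient="records")
    return PatternSet(values=values, manifest=manifest)


def dataset_checksum(arrays: dict[str, np.ndarray]) -> str:
    """Stable content hash over named arrays (regeneration check)."""
    import hashlib

    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        arr = np.ascontiguousarray(arrays[name])
        h.update(str(arr.dtype).encode())
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    return h.hexdigest()
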