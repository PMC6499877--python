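"""Run preprocessing and trial voxel-pattern extraction.

Two distinct z-normalizations are used and named explicitly:
``znormalize_run`` standardizes each voxel *over time* (removing signal
offsets and inter-run variance), while pattern extraction standardizes
each trial pattern *across voxels* (spatial z-scoring). Trial patterns
average the volumes at onset+2 and onset+3 (6-9 s after onset at TR 3 s,
on the hemodynamic peak).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import LETTERS
from .synth import RunDesign, SessionData

Z_TOL = 1e-6


def highpass_fourier(ts: np.ndarray, n_cycles: int = 3) -> np.ndarray:
    """High-pass filter a (v, T) run via a GLM Fourier basis.

    Regresses out an intercept, a linear trend, and sine/cosine pairs at
    1..n_cycles cycles per run, returning the residual (2 + 2*n_cycles
    regressors; 8 by default).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    T = ts.shape[1]
    n_reg = 2 + 2 * n_cycles
    if T < n_reg:
        raise ValueError(f"need at least {n_reg} volumes, got {T}")
    t = np.arange(T)
    cols = [np.ones(T), t - t.mean()]
    for c in range(1, n_cycles + 1):
        arg = 2 * np.pi * c * t / T
        cols += [np.sin(arg), np.cos(arg)]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def znormalize_run(ts: np.ndarray) -> np.ndarray:
    """Z-normalize each voxel's series over time (mean 0, sd 1).

    Constant voxel series cannot be standardized; they are flagged with a
    warning and set to zero (effectively excluding them from patterns).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    sd = ts.std(axis=1, keepdims=True)
    flat = (sd.ravel() == 0)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant voxel series set to zero", stacklevel=2
        )
    out = ts - ts.mean(axis=1, keepdims=True)
    np.divide(out, sd, out=out, where=sd > 0)
    return out


def znormalize_pattern(values: np.ndarray) -> np.ndarray:
    """Z-normalize one pattern across voxels; rejects constant patterns."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("constant pattern across voxels cannot be z-normalized")
    return (values - values.mean()) / sd


@dataclass
class VoxelPattern:
    """One z-normalized (across voxels) activation pattern."""

    values: np.ndarray
    letter: str
    condition: str  # perception | imagery
    run: int = 0
    trial: int = -1
    kind: str = "single_trial"  # single_trial | average

    def __post_init__(self) -> None:
        v = self.values
        if abs(v.mean()) > Z_TOL or abs(v.std() - 1.0) > Z_TOL:
            raise ValueError("pattern violates the z-normalization contract")


@dataclass
class PatternSet:
    """Patterns stacked as (n, v) with a tidy manifest."""

    values: np.ndarray
    manifest: pd.DataFrame  # columns: letter, condition, run, trial, kind

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.manifest):
            raise ValueError("manifest does not match pattern count")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, **conditions) -> "PatternSet":
        mask = np.ones(len(self.manifest), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.manifest[col] == val).to_numpy()
        return PatternSet(
            values=self.values[mask],
            manifest=self.manifest[mask].reset_index(drop=True),
        )

    def counts(self) -> pd.Series:
        return self.manifest.groupby(["condition", "letter"]).size()


def extract_trial_patterns(
    run_ts: np.ndarray,
    run: RunDesign,
    run_index: int = 0,
    window: tuple[int, int] = (2, 3),
) -> PatternSet:
    """Single-trial patterns from one run: mean of the volumes at
    onset+window[0] .. onset+window[1] (inclusive), z-scored across voxels.

    Trials whose window extends past the run end are dropped with a warning.
    """
    run_ts = np.atleast_2d(np.asarray(run_ts, dtype=float))
    lo, hi = window
    if not 0 <= lo <= hi:
        raise ValueError("window must satisfy 0 <= lo <= hi")
    rows, meta = [], []
    for trial, (onset, label) in enumerate(zip(run.onsets, run.labels)):
        if onset + hi >= run_ts.shape[1]:
            warnings.warn(
                f"trial {trial} (onset {onset}) too close to run end; dropped",
                stacklevel=2,
            )
            continue
        vals = run_ts[:, onset + lo : onset + hi + 1].mean(axis=1)
        rows.append(znormalize_pattern(vals))
        meta.append(
            dict(letter=label, condition=run.run_type, run=run_index,
                 trial=trial, kind="single_trial")
        )
    if not rows:
        raise ValueError("no extractable trials in run")
    return PatternSet(values=np.asarray(rows), manifest=pd.DataFrame(meta))


def extract_session_patterns(
    session: SessionData, window: tuple[int, int] = (2, 3), highpass: bool = True
) -> PatternSet:
    """Extract all perception and imagery single-trial patterns of a
    simulated session (high-pass + run z-normalization first)."""
    parts = []
    for i, (ts, run) in enumerate(zip(session.run_ts, session.design.runs)):
        if run.run_type == "mapping":
            continue
        if highpass:
            ts = highpass_fourier(ts)
        ts = znormalize_run(ts)
        parts.append(extract_trial_patterns(ts, run, run_index=i, window=window))
    values = np.concatenate([p.values for p in parts])
    manifest = pd.concat([p.manifest for p in parts], ignore_index=True)
    return PatternSet(values=values, manifest=manifest)


def average_letter_patterns(pset: PatternSet, condition: str) -> dict[str, VoxelPattern]:
    """Per-letter average pattern: mean of single trials, re-z-scored.

    Averages +x and -x patterns that cancel to a constant are rejected by
    the z-normalization (degenerate case).
    """
    out = {}
    sub = pset.subset(condition=condition)
    for L in LETTERS:
        mask = (sub.manifest["letter"] == L).to_numpy()
        if not mask.any():
            raise ValueError(f"no {condition} trials for letter {L!r}")
        mean = sub.values[mask].mean(axis=0)
        out[L] = VoxelPattern(
            values=znormalize_pattern(mean),
            letter=L,
            condition=condition,
            kind="average",
        )
    return out
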