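"""Shared fixtures: small synthetic subjects generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import prfdecode as pfd


@pytest.fixture(scope="session")
def grid80() -> pfd.VisualFieldGrid:
    return pfd.VisualFieldGrid(80, 80, 10.0)


@pytest.fixture(scope="session")
def letters80(grid80) -> dict:
    return pfd.render_letter_set(grid80)


@pytest.fixture(scope="session")
def hrf() -> pfd.HRFSpec:
    return pfd.HRFSpec()


@pytest.fixture(scope="session")
def small_subject(letters80, hrf):
    """One simulated subject at desk scale: 400 voxels, default design
    (4 imagery runs x 32 trials, one perception run of 32 trials)."""
    grid = letters80["H"].grid
    pop = pfd.sample_population(
        400, grid.extent / np.sqrt(2), slope=0.2, seed=11,
        noise_sd=1.0, imagery_gain=0.5, imagery_noise_sd=2.0,
    )
    design = pfd.make_session_design(seed=12)
    session = pfd.generate_session(pop, design, letters80, hrf, seed=13)
    return session


@pytest.fixture(scope="session")
def small_patterns(small_subject) -> pfd.PatternSet:
    return pfd.extract_session_patterns(small_subject)


@pytest.fixture(scope="session")
def perceptual_averages(small_patterns) -> np.ndarray:
    avg = pfd.average_letter_patterns(small_patterns, "perception")
    return np.vstack([avg[L].values for L in pfd.LETTERS])


@pytest.fixture(scope="session")
def trained_ae(perceptual_averages) -> pfd.AutoencoderParams:
    return pfd.train_autoencoder(
        perceptual_averages, pfd.autoencoder_config(seed=14)
    )
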