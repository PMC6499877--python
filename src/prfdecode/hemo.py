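"""Hemodynamic response: canonical double-gamma kernel sampled at the TR.

The kernel links neural drive (pRF-stimulus overlap per volume) to the
BOLD-like signal by discrete convolution. With a 6 s peak and TR = 3 s the
+2..+3 volume trial window (6-9 s after onset) straddles the response peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF: positive lobe minus scaled undershoot.

    ``peak_delay`` and ``undershoot_delay`` are the modes (seconds) of the
    two gamma densities (shape = delay + 1, unit scale); ``ratio`` scales
    the undershoot. Sampled at one value per TR over ``duration`` seconds.
    """

    tr: float = 3.0
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    ratio: float = 1.0 / 6.0
    duration: float = 33.0

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.duration <= self.tr:
            raise ValueError("need tr > 0 and duration > tr")
        if self.peak_delay <= 0 or self.undershoot_delay <= self.peak_delay:
            raise ValueError("need 0 < peak_delay < undershoot_delay")

    def kernel(self) -> np.ndarray:
        """HRF samples at t = 0, TR, 2 TR, ...; positive total integral."""
        t = np.arange(0.0, self.duration, self.tr)
        k = stats.gamma.pdf(t, a=self.peak_delay + 1) - self.ratio * stats.gamma.pdf(
            t, a=self.undershoot_delay + 1
        )
        if k.sum() <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")
        return k


def convolve_hrf(drive: np.ndarray, hrf: HRFSpec) -> np.ndarray:
    """Causal convolution of per-volume drive with the HRF kernel.

    ``drive`` has time on the last axis; output is truncated to the input
    length (no acausal leakage).
    """
    from scipy.signal import fftconvolve

    drive = np.asarray(drive, dtype=float)
    k = hrf.kernel()
    n = drive.shape[-1]
    shape = (1,) * (drive.ndim - 1) + (k.size,)
    return fftconvolve(drive, k.reshape(shape), axes=drive.ndim - 1)[..., :n]
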