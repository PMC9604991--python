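"""Synchrony, metastability and spectral summaries of simulated dynamics.

Global synchrony is the Kuramoto order parameter of the ensembles' mean
phases, R = |(1/E) sum_n e^{i psi_n}|; metastability is the standard
deviation of a synchrony measure over time.  Simulated neural activity is
the imaginary part of the complex order parameter, r sin(psi).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .model import Trajectory

__all__ = [
    "SynchronySummary",
    "global_kop",
    "sd_over_time",
    "neural_signal",
    "peak_frequency",
    "summarize",
]


@dataclass
class SynchronySummary:
    """Scalar dynamical descriptors of one simulation run.

    ``mean_R``/``global_meta`` are the time average and temporal SD of the
    global order parameter; ``mean_local``/``local_meta`` average the local
    synchrony (and its temporal SD) over ensembles.
    """

    mean_R: float
    global_meta: float
    mean_local: float
    local_meta: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def global_kop(psi_row: np.ndarray) -> float | np.ndarray:
    """Modulus of the mean phasor over ensembles.

    Accepts a single phase vector (returns a scalar) or a T x E array
    (returns the R time series).
    """
    psi = np.asarray(psi_row, dtype=float)
    R = np.abs(np.exp(1j * psi).mean(axis=-1))
    return float(R) if R.ndim == 0 else R


def sd_over_time(series: np.ndarray) -> float:
    """Population (moment) standard deviation over time samples."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    return float(series.std(axis=0, ddof=0)) if series.ndim == 1 else series.std(axis=0, ddof=0)


def neural_signal(traj: Trajectory) -> np.ndarray:
    """Projected neural activity: imaginary part of r e^{i psi}, shape T x E."""
    return traj.r * np.sin(traj.psi)


def peak_frequency(x: np.ndarray, fs: float) -> float:
    """Dominant frequency of a 1-D signal via a Welch periodogram.

    Uses 4-second segments (0.25 Hz resolution) and searches [1, fs/2) Hz,
    excluding the DC/infra-slow region.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 seconds of samples")
    nperseg = min(x.size, int(round(4 * fs)))
    freqs, power = sps.welch(x, fs=fs, nperseg=nperseg)
    band = (freqs >= 1.0) & (freqs < fs / 2)
    if not np.any(power[band] > 0):
        raise ValueError("signal has no spectral peak above 1 Hz")
    return float(freqs[band][np.argmax(power[band])])


def summarize(traj: Trajectory, t_transient: float = 0.0) -> SynchronySummary:
    """Synchrony/metastability summary over t >= t_transient."""
    part = traj.from_time(t_transient)
    R = global_kop(part.psi)
    local_sd = part.r.std(axis=0, ddof=0)
    return SynchronySummary(
        mean_R=float(R.mean()),
        global_meta=float(R.std(ddof=0)),
        mean_local=float(part.r.mean()),
        local_meta=float(local_sd.mean()),
    )
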