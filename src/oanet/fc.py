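"""Amplitude-envelope functional connectivity.

The same pipeline is applied to simulated activity and to pre-parcellated
empirical signals: band-pass 8-13 Hz (zero-phase Butterworth), Hilbert
envelope, low-pass 0.5 Hz, downsample to 5 Hz, trim one second from each
end.  Static FC (sFC) is the Pearson correlation matrix of the envelopes;
time-resolved FC is summarized by the recurrence distribution -- the
correlations between window-wise sFC matrices over a 15 s sliding window
with 12 s overlap -- and recurrence distributions are compared with the
two-sample Kolmogorov-Smirnov statistic.  Simulated signals are not
orthogonalized (there is no source leakage to correct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.fft import next_fast_len

__all__ = [
    "EnvelopeSet",
    "FCMatrix",
    "RecurrenceSample",
    "alpha_envelope",
    "static_fc",
    "fc_similarity",
    "trfc_recurrence",
    "ks_distance",
    "nodal_strength",
    "upper_triangle",
]

FCMatrix = np.ndarray  # E x E symmetric Pearson-correlation matrix


@dataclass
class EnvelopeSet:
    """Downsampled band-limited amplitude envelopes, shape T' x E."""

    env: np.ndarray
    fs_env: float = 5.0

    def __post_init__(self) -> None:
        self.env = np.atleast_2d(np.asarray(self.env, dtype=float))
        if np.any(self.env < 0):
            raise ValueError("envelopes must be nonnegative")


@dataclass
class RecurrenceSample:
    """Pairwise window-FC correlations underlying the recurrence histogram."""

    values: np.ndarray
    window_s: float
    overlap_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def alpha_envelope(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (8.0, 13.0),
    env_lowpass: float = 0.5,
    fs_env: float = 5.0,
    edge_trim_s: float = 1.0,
) -> EnvelopeSet:
    """Extract low-frequency amplitude envelopes of band-limited activity.

    Zero-phase (forward-backward) 4th-order Butterworth filters are used
    for both the band-pass and the envelope low-pass.  The analytic-signal
    magnitude is computed with the Hilbert transform, the envelope is
    low-pass filtered, decimated to ``fs_env``, and one second is trimmed
    from each end to drop filter edge artifacts.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if fs < 2.5 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for a {band[1]} Hz band edge")
    if n < 4 * fs:
        raise ValueError("need at least 4 seconds of signal")
    sos_bp = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos_bp, x, axis=0)
    nfft = next_fast_len(n)
    env = np.abs(sps.hilbert(xb, N=nfft, axis=0)[:n])
    sos_lp = sps.butter(4, env_lowpass, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos_lp, env, axis=0)
    step = int(round(fs / fs_env))
    env = env[::step]
    trim = int(round(edge_trim_s * fs_env))
    if trim:
        env = env[trim:-trim]
    # zero-phase filtering of a nonnegative envelope can undershoot slightly
    return EnvelopeSet(np.maximum(env, 0.0), fs_env=fs_env)


def static_fc(env: EnvelopeSet | np.ndarray) -> FCMatrix:
    """Pearson correlation matrix of region envelopes (unit diagonal)."""
    e = env.env if isinstance(env, EnvelopeSet) else np.asarray(env, dtype=float)
    if e.shape[0] < 10:
        raise ValueError("need at least 10 envelope samples")
    dead = np.flatnonzero(np.ptp(e, axis=0) == 0)
    if dead.size:
        raise ValueError(f"region {dead[0]} has zero envelope variance")
    fc = np.corrcoef(e, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def upper_triangle(m: np.ndarray) -> np.ndarray:
    """Strict upper-triangle entries of a square matrix as a flat vector."""
    m = np.asarray(m)
    return m[np.triu_indices(m.shape[0], k=1)]


def fc_similarity(a: FCMatrix, b: FCMatrix) -> float:
    """Pearson correlation between the upper triangles of two FC matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"FC shape mismatch: {a.shape} vs {b.shape}")
    return float(np.corrcoef(upper_triangle(a), upper_triangle(b))[0, 1])


def trfc_recurrence(
    env: EnvelopeSet, window_s: float = 15.0, overlap_s: float = 12.0
) -> RecurrenceSample:
    """Recurrence of window-wise FC: correlations between all window pairs.

    Windows of ``window_s`` seconds advance by ``window_s - overlap_s``;
    sFC is computed within each window and every pair of windows yields
    one Pearson correlation between their upper-triangle FC vectors.
    """
    e = env.env
    win = int(round(window_s * env.fs_env))
    step = int(round((window_s - overlap_s) * env.fs_env))
    if step <= 0:
        raise ValueError("overlap must be shorter than the window")
    n_win = (e.shape[0] - win) // step + 1
    if n_win < 2:
        raise ValueError("need at least 2 windows for recurrence")
    vecs = np.empty((n_win, e.shape[1] * (e.shape[1] - 1) // 2))
    for w in range(n_win):
        vecs[w] = upper_triangle(static_fc(EnvelopeSet(e[w * step : w * step + win], env.fs_env)))
    corr = np.corrcoef(vecs)
    return RecurrenceSample(upper_triangle(corr), window_s, overlap_s)


def ks_distance(a: RecurrenceSample | np.ndarray, b: RecurrenceSample | np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between recurrence samples."""
    av = a.values if isinstance(a, RecurrenceSample) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, RecurrenceSample) else np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("recurrence samples must be non-empty")
    return float(stats.ks_2samp(av, bv, method="asymp").statistic)


def nodal_strength(fc: FCMatrix) -> np.ndarray:
    """Nodal FC strength: row sums of the FC matrix excluding the diagonal."""
    fc = np.asarray(fc, dtype=float)
    return fc.sum(axis=1) - np.diag(fc)
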