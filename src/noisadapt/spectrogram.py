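"""Cochlear-model auditory spectrogram and derived views.

The time-frequency representation mimics peripheral auditory processing:
a bank of constant-Q asymmetric (gammatone) bandpass filters spaced on a
logarithmic frequency axis, a compressive nonlinearity, a first-order
difference across adjacent bands (lateral inhibition), half-wave
rectification, and short-time envelope extraction framed at ``frame_rate``.

The 128-band output is typically reduced to 13 log-spaced bands by local
averaging before decoding, matching the dimensionality used for the
reconstruction analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "Spectrogram",
    "cochlear_spectrogram",
    "reduce_bands",
    "frequency_profile",
    "temporal_envelope",
]


@dataclass
class Spectrogram:
    """Time x frequency non-negative power matrix.

    Attributes
    ----------
    values : ndarray, shape (n_frames, n_bands)
    frame_rate : float, Hz
    center_freqs : ndarray, Hz, strictly increasing (log-spaced)
    """

    values: np.ndarray
    frame_rate: float
    center_freqs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x frequency)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.center_freqs is None:
            self.center_freqs = np.arange(self.values.shape[1], dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.center_freqs.size != self.values.shape[1]:
            raise ValueError("center_freqs length must match frequency axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        """Frame onset times; frame t covers [t/fr, (t+1)/fr), half-open."""
        return np.arange(self.n_frames) / self.frame_rate


def log_center_freqs(n_filters: int, f_lo: float, f_hi: float) -> np.ndarray:
    return np.geomspace(f_lo, f_hi, n_filters)


def cochlear_spectrogram(
    wave: np.ndarray,
    fs: float,
    n_filters: int = 128,
    frame_rate: float = 100.0,
    f_lo: float = 180.0,
    f_hi: float = 5400.0,
    compression: float = 1.0 / 3.0,
) -> Spectrogram:
    """Cochlear-model spectrogram of a mono waveform.

    Stages: gammatone filterbank on a log-spaced axis -> power-law
    compression (default cube root) -> first-order difference across
    adjacent bands, half-wave rectified -> envelope extraction by
    rectified-mean over each frame window.

    The frame-rate contract is ``n_frames = floor(n_samples * frame_rate /
    fs)``; trailing samples short of a full frame are dropped.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1 or wave.size == 0:
        raise ValueError("wave must be a non-empty 1-D array")
    if not np.all(np.isfinite(wave)):
        raise ValueError("wave contains non-finite samples")
    if fs < 2.0 * f_hi:
        raise ValueError(f"fs={fs} too low for highest filter {f_hi} Hz")
    cfs = log_center_freqs(n_filters, f_lo, f_hi)
    samples_per_frame = int(round(fs / frame_rate))
    n_frames = wave.size // samples_per_frame
    if n_frames == 0:
        raise ValueError("waveform shorter than one frame")
    usable = n_frames * samples_per_frame

    out = np.empty((n_frames, n_filters))
    prev = None
    for k, cf in enumerate(cfs):
        b, a = _sig.gammatone(cf, "iir", fs=fs)
        y = _sig.lfilter(b, a, wave)
        # compress magnitude, keep sign, so the spectral difference sees
        # signed band outputs (cbrt fast path for the default exponent)
        if abs(compression - 1.0 / 3.0) < 1e-12:
            y = np.cbrt(y)
        elif compression != 1.0:
            y = np.sign(y) * np.abs(y) ** compression
        if prev is None:
            d = y  # lowest band: no lower neighbour to subtract
        else:
            d = y - prev
        prev = y
        env = np.clip(d, 0.0, None)[:usable]
        out[:, k] = env.reshape(n_frames, samples_per_frame).mean(axis=1)
    return Spectrogram(out, frame_rate, cfs)


def reduce_bands(spec: Spectrogram, n_out: int = 13) -> Spectrogram:
    """Resample the frequency axis to ``n_out`` log-spaced bands.

    Each output band averages the input bands whose (log) centre frequency
    falls in its bin; bins are equal width in log frequency, so a flat
    input stays flat and the per-frame mean power is conserved.
    """
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    n_in = spec.n_bands
    if n_out > n_in:
        raise ValueError("n_out must not exceed the input band count")
    if n_out == n_in:
        return Spectrogram(spec.values.copy(), spec.frame_rate, spec.center_freqs.copy())
    logf = np.log(spec.center_freqs)
    edges = np.linspace(logf[0], logf[-1], n_out + 1)
    # assign each input band to an output bin (rightmost band into last bin)
    bins = np.clip(np.searchsorted(edges, logf, side="right") - 1, 0, n_out - 1)
    vals = np.zeros((spec.n_frames, n_out))
    cfs = np.empty(n_out)
    for j in range(n_out):
        members = bins == j
        if not members.any():  # can't happen for n_out << n_in, guard anyway
            raise ValueError(f"empty output band {j}; reduce n_out")
        vals[:, j] = spec.values[:, members].mean(axis=1)
        cfs[j] = np.exp(logf[members].mean())
    return Spectrogram(vals, spec.frame_rate, cfs)


def frequency_profile(
    spec: Spectrogram,
    interval: tuple[float, float] | None = None,
    peak_normalize: bool = False,
) -> np.ndarray:
    """Time-averaged power per band over ``interval`` = [start_s, end_s).

    With ``peak_normalize`` the profile is scaled to a maximum of 1
    (undefined and returned as-is for an all-zero profile).
    """
    if interval is None:
        frames = spec.values
    else:
        start_s, end_s = interval
        i0 = int(np.floor(start_s * spec.frame_rate))
        i1 = int(np.floor(end_s * spec.frame_rate))
        i0 = max(i0, 0)
        i1 = min(i1, spec.n_frames)
        if i1 <= i0:
            raise ValueError("empty interval")
        frames = spec.values[i0:i1]
    prof = frames.mean(axis=0)
    if peak_normalize:
        peak = prof.max()
        if peak > 0:
            prof = prof / peak
    return prof


def temporal_envelope(spec: Spectrogram) -> np.ndarray:
    """Mean across frequency per frame (the broadband envelope)."""
    return spec.values.mean(axis=1)
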