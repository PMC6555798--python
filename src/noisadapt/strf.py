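"""Spectrotemporal receptive field estimation and tuning characterization.

The STRF is the linear kernel mapping the stimulus spectrogram to a site's
response. It is estimated by normalized reverse correlation: the
stimulus-response cross-correlation normalized by the stimulus
autocorrelation, with ridge shrinkage,

    w = (X'X + lambda I)^{-1} X' y

on the mean-centred lagged stimulus design X. The ridge penalty can be
fixed or selected by cross-validation over contiguous folds (``reg="cv"``),
which respects the temporal autocorrelation of natural stimuli.

Derived tuning scalars:

* best frequency / latency — power-weighted centroid of the excitatory
  region (the connected component of kernel values >= theta x max positive
  value that contains the maximum, default theta = 0.5) along the frequency
  and lag axes;
* best rate — from the rate-scale (modulation) spectrum: the 2-D Fourier
  magnitude of the kernel mapped to (rate Hz, scale cycles/octave) axes and
  folded over rate sign; the rate vector averages power over all non-rate
  dimensions and the best rate is its power-weighted mean.

Speech specificity is a separate, model-free t-value per electrode
contrasting mean responses to speech vs nonspeech sound events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

from ._design import lagged_design_causal
from .preprocess import NeuralRecording
from .spectrogram import Spectrogram
from .stats import unpaired_t

__all__ = [
    "STRF",
    "STRFResults",
    "best_frequency",
    "response_latency",
    "modulation_spectrum",
    "best_rate",
    "speech_specificity",
]

DEFAULT_REG_GRID = np.geomspace(1e-4, 1e2, 7)


class STRF:
    """Forward encoding model: stimulus spectrogram -> response.

    Parameters
    ----------
    stim : Spectrogram (any band count; typically the 13-band reduction)
    resp : 1-D array (single electrode), 2-D array (electrodes x time) or
        NeuralRecording at the stimulus frame rate
    max_lag_ms : kernel lag span, 0..max_lag_ms
    """

    def __init__(self, stim: Spectrogram, resp, max_lag_ms: float = 250.0):
        if isinstance(resp, NeuralRecording):
            if abs(resp.fs - stim.frame_rate) > 1e-9:
                raise ValueError("response and stimulus sampling rates differ")
            resp = resp.response
        resp = np.atleast_2d(np.asarray(resp, dtype=float))
        if resp.shape[1] != stim.n_frames:
            raise ValueError("stimulus and response lengths differ")
        if not np.any(stim.values):
            raise ValueError("all-zero stimulus: autocorrelation is singular")
        self.stim = stim
        self.resp = resp
        self.n_lags = int(round(max_lag_ms * stim.frame_rate / 1000.0)) + 1
        self.lag_axis_ms = np.arange(self.n_lags) * 1000.0 / stim.frame_rate
        self.freq_axis = stim.center_freqs

    def fit(self, reg="cv", cv_folds: int = 5, reg_grid=None) -> "STRFResults":
        """Solve the regularized normal equations.

        ``reg`` is either a non-negative ridge penalty (in units of the mean
        stimulus-design diagonal power, making it scale-free) or ``"cv"``,
        which picks the grid value maximizing mean held-out prediction
        correlation over contiguous folds.
        """
        X = lagged_design_causal(self.stim.values, self.n_lags)
        Y = self.resp.T  # T x n_el
        xm = X.mean(axis=0)
        ym = Y.mean(axis=0)
        Xc = X - xm
        Yc = Y - ym
        G = Xc.T @ Xc
        C = Xc.T @ Yc
        p = G.shape[0]
        scale = np.trace(G) / p  # mean diagonal power; makes reg scale-free

        if reg == "cv":
            grid = DEFAULT_REG_GRID if reg_grid is None else np.asarray(reg_grid, float)
            reg_per_el, cv_corr = self._cross_validate(Xc, Yc, grid, cv_folds, scale)
        else:
            reg = float(reg)
            if reg < 0:
                raise ValueError("reg must be non-negative")
            if reg == 0 and p > X.shape[0]:
                raise ValueError("more parameters than frames requires reg > 0")
            reg_per_el = np.full(self.resp.shape[0], reg)
            cv_corr = None

        n_el = self.resp.shape[0]
        W = np.empty((p, n_el))
        for lam in np.unique(reg_per_el):
            cols = reg_per_el == lam
            A = G + lam * scale * np.eye(p)
            W[:, cols] = np.linalg.solve(A, C[:, cols])
        kernels = W.T.reshape(n_el, self.n_lags, self.stim.n_bands)
        return STRFResults(
            kernels=kernels,
            lag_axis_ms=self.lag_axis_ms,
            freq_axis=np.asarray(self.freq_axis, float),
            regularization=reg_per_el,
            cv_correlation=cv_corr,
            intercept=ym - xm @ W,
            model=self,
        )

    def _cross_validate(self, Xc, Yc, grid, n_folds, scale):
        T, p = Xc.shape
        n_el = Yc.shape[1]
        bounds = np.linspace(0, T, n_folds + 1).astype(int)
        corr = np.zeros((grid.size, n_el))
        for f in range(n_folds):
            lo, hi = bounds[f], bounds[f + 1]
            tr = np.ones(T, dtype=bool)
            tr[lo:hi] = False
            Xtr, Ytr = Xc[tr], Yc[tr]
            Xte, Yte = Xc[lo:hi], Yc[lo:hi]
            G = Xtr.T @ Xtr
            C = Xtr.T @ Ytr
            for gi, lam in enumerate(grid):
                W = np.linalg.solve(G + lam * scale * np.eye(p), C)
                pred = Xte @ W
                pc = pred - pred.mean(axis=0)
                yc = Yte - Yte.mean(axis=0)
                num = (pc * yc).sum(axis=0)
                den = np.sqrt((pc**2).sum(axis=0) * (yc**2).sum(axis=0))
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.where(den > 0, num / den, 0.0)
                corr[gi] += r / n_folds
        best = np.argmax(corr, axis=0)
        return grid[best], corr[best, np.arange(n_el)]


@dataclass
class STRFResults:
    """Fitted kernels plus derived tuning parameters."""

    kernels: np.ndarray  # n_el x n_lags x n_bands
    lag_axis_ms: np.ndarray
    freq_axis: np.ndarray
    regularization: np.ndarray
    cv_correlation: np.ndarray | None
    intercept: np.ndarray
    model: STRF = field(repr=False, default=None)

    @property
    def n_electrodes(self) -> int:
        return self.kernels.shape[0]

    @property
    def kernel(self) -> np.ndarray:
        """Single-electrode convenience accessor."""
        if self.n_electrodes != 1:
            raise ValueError("multiple electrodes; index .kernels explicitly")
        return self.kernels[0]

    def best_frequency(self, i: int = 0, theta: float = 0.5) -> float:
        return best_frequency(self.kernels[i], self.freq_axis, theta)

    def response_latency(self, i: int = 0, theta: float = 0.5) -> float:
        return response_latency(self.kernels[i], self.lag_axis_ms, theta)

    def best_rate(self, i: int = 0, weighting: str = "power") -> float:
        return best_rate(self.kernels[i], self.lag_axis_ms, self.freq_axis, weighting)

    def tuning_table(self):
        """Per-electrode tuning parameters as a DataFrame."""
        import pandas as pd

        rows = []
        for i in range(self.n_electrodes):
            try:
                bf = self.best_frequency(i)
                lat = self.response_latency(i)
            except ValueError:  # no excitatory region
                bf, lat = np.nan, np.nan
            try:
                br = self.best_rate(i)
            except ValueError:
                br = np.nan
            rows.append({"electrode": i, "best_freq_hz": bf, "latency_ms": lat,
                         "best_rate_hz": br, "regularization": self.regularization[i]})
        return pd.DataFrame(rows)

    def predict(self, stim: Spectrogram) -> np.ndarray:
        """Linear prediction of responses (electrodes x frames)."""
        X = lagged_design_causal(stim.values, self.lag_axis_ms.size)
        return (X @ self.kernels.reshape(self.n_electrodes, -1).T + self.intercept).T

    def summary(self) -> str:
        tab = self.tuning_table()
        lines = [
            "STRF fit: %d electrode(s), %d lags (0-%.0f ms), %d bands"
            % (self.n_electrodes, self.lag_axis_ms.size, self.lag_axis_ms[-1],
               self.freq_axis.size),
        ]
        if self.cv_correlation is not None:
            lines.append("mean CV prediction r = %.3f" % np.nanmean(self.cv_correlation))
        lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)


def _excitatory_region(kernel: np.ndarray, theta: float):
    """Connected component (4-connectivity) of values >= theta * max
    positive value that contains the global maximum."""
    mx = kernel.max()
    if mx <= 0:
        raise ValueError("kernel has no positive (excitatory) region")
    mask = kernel >= theta * mx
    labels, _ = _ndi.label(mask)
    peak = np.unravel_index(np.argmax(kernel), kernel.shape)
    region = labels == labels[peak]
    return region


def best_frequency(kernel: np.ndarray, freq_axis: np.ndarray, theta: float = 0.5) -> float:
    """Power-weighted centroid (on the log-frequency axis) of the
    excitatory region; returned in Hz."""
    region = _excitatory_region(kernel, theta)
    w = np.where(region, kernel, 0.0)
    band_w = w.sum(axis=0)
    logf = np.log2(np.asarray(freq_axis, float))
    return float(2.0 ** (np.sum(band_w * logf) / band_w.sum()))


def response_latency(kernel: np.ndarray, lag_axis_ms: np.ndarray, theta: float = 0.5) -> float:
    """Power-weighted centroid of the excitatory region along lag (ms)."""
    region = _excitatory_region(kernel, theta)
    w = np.where(region, kernel, 0.0)
    lag_w = w.sum(axis=1)
    return float(np.sum(lag_w * np.asarray(lag_axis_ms, float)) / lag_w.sum())


def modulation_spectrum(
    kernel: np.ndarray,
    lag_axis_ms: np.ndarray,
    freq_axis: np.ndarray,
    n_fft_rate: int = 256,
    n_fft_scale: int = 64,
):
    """Rate-scale power spectrum of a kernel.

    Windowed 2-D FFT magnitude squared, folded over the rate sign (upward
    and downward sweeps pooled) and over the scale sign. Returns
    ``(power, rate_axis_hz, scale_axis_cyc_per_oct)`` with non-negative
    increasing axes (rate axis includes 0).
    """
    if not np.any(kernel):
        raise ValueError("all-zero kernel has no modulation spectrum")
    dt = (lag_axis_ms[1] - lag_axis_ms[0]) / 1000.0
    logf = np.log2(np.asarray(freq_axis, float))
    df_oct = np.mean(np.diff(logf))  # bands are log-spaced
    F = np.fft.fft2(kernel, s=(n_fft_rate, n_fft_scale))
    P = np.abs(F) ** 2
    nr = n_fft_rate // 2
    nsc = n_fft_scale // 2
    # fold the four sign quadrants onto non-negative (rate, scale) axes,
    # pooling upward/downward sweep directions
    ir = np.arange(nr + 1)
    js = np.arange(nsc + 1)
    irn = (-ir) % n_fft_rate
    jsn = (-js) % n_fft_scale
    folded = (
        P[np.ix_(ir, js)] + P[np.ix_(irn, js)] + P[np.ix_(ir, jsn)] + P[np.ix_(irn, jsn)]
    ) / 4.0
    rate_axis = np.arange(nr + 1) / (n_fft_rate * dt)
    scale_axis = np.arange(nsc + 1) / (n_fft_scale * df_oct)
    return folded, rate_axis, scale_axis


def best_rate(
    kernel: np.ndarray,
    lag_axis_ms: np.ndarray,
    freq_axis: np.ndarray,
    weighting: str = "power",
) -> float:
    """Preferred temporal modulation rate (Hz).

    ``weighting="power"`` (default): power-weighted mean of the rate axis,
    sum(r P(r)) / sum(P(r)), where the rate vector P averages the folded
    rate-scale power over scale. ``weighting="literal"`` implements the
    alternative reading in which the rate values themselves are the
    weights: sum(r P(r)) / sum(r).
    """
    P, rates, _ = modulation_spectrum(kernel, lag_axis_ms, freq_axis)
    rate_vec = P.mean(axis=1)
    if weighting == "power":
        return float(np.sum(rates * rate_vec) / np.sum(rate_vec))
    if weighting == "literal":
        return float(np.sum(rates * rate_vec) / np.sum(rates))
    raise ValueError("weighting must be 'power' or 'literal'")


def speech_specificity(rec: NeuralRecording, sound_events) -> np.ndarray:
    """Per-electrode speech-specificity t-value.

    ``sound_events`` is a list of ``((start_s, end_s), is_speech)``. Each
    event contributes its mean normalized response; an unpaired t-test of
    speech minus nonspeech events gives one t per electrode (positive =
    speech-preferring).
    """
    speech, nonspeech = [], []
    for (start_s, end_s), is_speech in sound_events:
        sl = rec._interval_slice(start_s, end_s)
        if sl.stop <= sl.start:
            raise ValueError(f"empty event interval ({start_s}, {end_s})")
        (speech if is_speech else nonspeech).append(rec.response[:, sl].mean(axis=1))
    if len(speech) < 2 or len(nonspeech) < 2:
        raise ValueError("need at least two events per class")
    sp = np.array(speech)
    ns = np.array(nonspeech)
    return np.array([unpaired_t(sp[:, e], ns[:, e])[0] for e in range(rec.n_electrodes)])
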