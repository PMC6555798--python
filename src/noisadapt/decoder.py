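"""Linear stimulus reconstruction (neural decoding) and noise-suppression
time-course analysis.

The decoder g maps lagged population responses back to the stimulus
spectrogram by ridge regression: minimizing the MSE between reconstructed
and original spectrograms yields the stimulus-response cross-correlation
normalized by the response autocorrelation. The model is trained on
clean-speech responses only and then applied to responses recorded during
the switching-noise task.

Lag convention: the neural response follows the stimulus, so stimulus
frame t is predicted from responses in [t, t + max_lag] ("-250 to 0 ms of
the neural data" relative to the reconstructed frame). A ``mirrored`` flag
provides the opposite convention for comparison.

Downstream analyses quantify how quickly noise features disappear from
the reconstruction after a background switch: a transition-aligned R^2
time course against the clean and noisy originals (whose crossing defines
the switching time), DA/AA frequency-profile similarities (the DA-vs-clean
value being the per-condition speech-masking index), and the duration of
the reconstruction's deviation from the clean envelope (the adaptation
interval of the reconstructed speech).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._design import lagged_design_anticausal, lagged_design_causal
from .preprocess import NeuralRecording
from .spectrogram import Spectrogram, frequency_profile, temporal_envelope
from .stats import paired_t
from .synth import TransitionSchedule

__all__ = [
    "StimulusDecoder",
    "DecoderResults",
    "r_squared",
    "r2_timecourse",
    "profile_similarity",
    "reconstruction_adaptation_interval",
]


def r_squared(pred: np.ndarray, ref: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of ``pred`` against
    ``ref`` (pooled over all elements); <= 1, can be negative."""
    pred = np.asarray(pred, float).ravel()
    ref = np.asarray(ref, float).ravel()
    ss_tot = np.sum((ref - ref.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("reference has zero variance")
    return float(1.0 - np.sum((pred - ref) ** 2) / ss_tot)


def regression_r2(pred: np.ndarray, ref: np.ndarray) -> float:
    """Signed squared Pearson correlation (the R^2 of the best affine fit
    of ``pred`` to ``ref``, negated for anticorrelation); robust to the
    arbitrary scale and offset of peak-normalized profiles."""
    pred = np.asarray(pred, float).ravel()
    ref = np.asarray(ref, float).ravel()
    pc = pred - pred.mean()
    rc = ref - ref.mean()
    den = np.sqrt((pc**2).sum() * (rc**2).sum())
    if den == 0:
        raise ValueError("zero-variance input")
    r = float((pc * rc).sum() / den)
    return r * abs(r)


class StimulusDecoder:
    """Backward model: lagged population responses -> spectrogram."""

    def __init__(
        self,
        resp: NeuralRecording,
        stim: Spectrogram,
        max_lag_ms: float = 250.0,
        mirrored: bool = False,
    ):
        if abs(resp.fs - stim.frame_rate) > 1e-9:
            raise ValueError("response and stimulus are misaligned (sampling rates)")
        if resp.n_samples != stim.n_frames:
            raise ValueError("response and stimulus are misaligned (lengths)")
        self.resp = resp
        self.stim = stim
        self.n_lags = int(round(max_lag_ms * stim.frame_rate / 1000.0)) + 1
        self.mirrored = mirrored

    def _design(self, response: np.ndarray) -> np.ndarray:
        build = lagged_design_causal if self.mirrored else lagged_design_anticausal
        return build(response.T, self.n_lags)

    def fit(self, ridge=1e-3, cv_folds: int = 5, ridge_grid=None) -> "DecoderResults":
        """Per-band ridge solution of the lagged-response design.

        ``ridge`` is scale-free (units of mean design diagonal power) or
        ``"cv"`` for contiguous-fold selection maximizing held-out
        reconstruction correlation (one shared penalty for all bands).
        """
        X = self._design(self.resp.response)
        Y = self.stim.values
        xm = X.mean(axis=0)
        ym = Y.mean(axis=0)
        Xc = X - xm
        Yc = Y - ym
        p = X.shape[1]
        G = Xc.T @ Xc
        scale = np.trace(G) / p
        if scale == 0:
            scale = 1.0  # all-zero responses: solution collapses to intercept

        if ridge == "cv":
            grid = np.geomspace(1e-4, 1e2, 7) if ridge_grid is None else np.asarray(ridge_grid, float)
            ridge = self._cross_validate(Xc, Yc, grid, cv_folds, scale)
        ridge = float(ridge)
        if ridge < 0:
            raise ValueError("ridge must be non-negative")
        if ridge == 0 and p > X.shape[0]:
            raise ValueError("more parameters than frames requires ridge > 0")
        W = np.linalg.solve(G + ridge * scale * np.eye(p), Xc.T @ Yc)
        return DecoderResults(
            weights=W,
            intercept=ym - xm @ W,
            n_lags=self.n_lags,
            frame_rate=self.stim.frame_rate,
            center_freqs=np.asarray(self.stim.center_freqs, float),
            ridge=ridge,
            mirrored=self.mirrored,
            electrode_ids=list(self.resp.electrode_ids),
        )

    def _cross_validate(self, Xc, Yc, grid, n_folds, scale):
        T, p = Xc.shape
        bounds = np.linspace(0, T, n_folds + 1).astype(int)
        score = np.zeros(grid.size)
        for f in range(n_folds):
            lo, hi = bounds[f], bounds[f + 1]
            tr = np.ones(T, dtype=bool)
            tr[lo:hi] = False
            G = Xc[tr].T @ Xc[tr]
            C = Xc[tr].T @ Yc[tr]
            for gi, lam in enumerate(grid):
                W = np.linalg.solve(G + lam * scale * np.eye(p), C)
                pred = Xc[lo:hi] @ W
                ref = Yc[lo:hi]
                pc = pred - pred.mean()
                rc = ref - ref.mean()
                den = np.sqrt((pc**2).sum() * (rc**2).sum())
                score[gi] += ((pc * rc).sum() / den if den > 0 else 0.0) / n_folds
        return float(grid[np.argmax(score)])


@dataclass
class DecoderResults:
    """Fitted reconstruction filter (one per training group/"subject")."""

    weights: np.ndarray  # (n_lags * n_el) x n_bands
    intercept: np.ndarray  # per band
    n_lags: int
    frame_rate: float
    center_freqs: np.ndarray
    ridge: float
    mirrored: bool
    electrode_ids: list = field(default_factory=list)
    training_group_id: str = "group0"

    @property
    def lag_axis_ms(self) -> np.ndarray:
        lags = np.arange(self.n_lags) * 1000.0 / self.frame_rate
        return -lags if not self.mirrored else lags

    def reconstruct(self, resp: NeuralRecording) -> Spectrogram:
        """Linear read-out per frame. The trailing ``n_lags - 1`` frames
        (leading, under the mirrored convention) lack full lag context and
        are zero-padded; ``self.last_valid_mask`` flags them after a call."""
        if list(resp.electrode_ids) != list(self.electrode_ids):
            raise ValueError("electrode set/order does not match the fitted filter")
        build = lagged_design_causal if self.mirrored else lagged_design_anticausal
        X = build(resp.response.T, self.n_lags)
        values = X @ self.weights + self.intercept
        valid = np.ones(values.shape[0], dtype=bool)
        if self.mirrored:
            valid[: self.n_lags - 1] = False
        else:
            valid[values.shape[0] - self.n_lags + 1 :] = False
        self.last_valid_mask = valid
        return Spectrogram(values, self.frame_rate, self.center_freqs)

    def summary(self) -> str:
        return (
            "StimulusDecoder: %d electrodes x %d lags -> %d bands, ridge=%g"
            % (len(self.electrode_ids), self.n_lags, self.intercept.size, self.ridge)
        )


def average_reconstructions(specs) -> Spectrogram:
    """Average per-group reconstructions (per-subject fit, then average)."""
    specs = list(specs)
    vals = np.mean([s.values for s in specs], axis=0)
    return Spectrogram(vals, specs[0].frame_rate, specs[0].center_freqs)


# ---------------------------------------------------------------------------
# noise-suppression time course
# ---------------------------------------------------------------------------

def _aligned_frames(schedule: TransitionSchedule, frame_rate: float, n_frames: int,
                    window_s: float, include_clean: bool):
    """Transition onsets (frame index, condition) with the full post-window
    inside the recording."""
    win = int(round(window_s * frame_rate))
    out = []
    for t_k, cond in schedule.transitions():
        if cond == "clean" and not include_clean:
            continue
        i0 = int(round(t_k * frame_rate))
        if i0 + win <= n_frames:
            out.append((i0, cond))
    return out, win


def r2_timecourse(
    recon: Spectrogram,
    clean_spec: Spectrogram,
    noisy_spec: Spectrogram,
    schedule: TransitionSchedule,
    window_s: float = 3.0,
    persist_s: float = 0.2,
    min_transitions: int = 10,
):
    """Transition-aligned R^2 of the reconstruction against the clean and
    the noisy original, and the switching time between them.

    At each aligned frame the R^2 pools residuals across frequency bands
    and all transitions into non-clean conditions. The switching time is
    the first post-transition frame at which R^2_clean exceeds R^2_noisy
    and stays higher for at least ``persist_s``; ``None`` if absent.

    Returns ``(r2_clean, r2_noisy, switch_time_ms)``.
    """
    for s in (clean_spec, noisy_spec):
        if s.n_frames != recon.n_frames or abs(s.frame_rate - recon.frame_rate) > 1e-9:
            raise ValueError("spectrograms are misaligned")
    trans, win = _aligned_frames(schedule, recon.frame_rate, recon.n_frames,
                                 window_s, include_clean=False)
    if len(trans) < min_transitions:
        raise ValueError(
            f"only {len(trans)} usable non-clean transitions (< {min_transitions})")
    idx = np.array([i for i, _ in trans])
    rec = np.stack([recon.values[i : i + win] for i in idx])  # K x win x B
    cl = np.stack([clean_spec.values[i : i + win] for i in idx])
    no = np.stack([noisy_spec.values[i : i + win] for i in idx])

    def r2_per_frame(ref):
        res = np.sum((rec - ref) ** 2, axis=(0, 2))
        mean = ref.mean(axis=(0, 2), keepdims=True)
        tot = np.sum((ref - mean) ** 2, axis=(0, 2))
        return 1.0 - res / tot

    r2_clean = r2_per_frame(cl)
    r2_noisy = r2_per_frame(no)

    persist = int(round(persist_s * recon.frame_rate))
    above = r2_clean > r2_noisy
    switch_ms = None
    for u in range(win - persist + 1):
        if above[u : u + persist].all():
            switch_ms = u * 1000.0 / recon.frame_rate
            break
    return r2_clean, r2_noisy, switch_ms


def profile_similarity(
    recon: Spectrogram,
    clean_spec: Spectrogram,
    noisy_spec: Spectrogram,
    schedule: TransitionSchedule,
    da: tuple[float, float] = (0.0, 0.4),
    aa: tuple[float, float] = (2.0, 2.4),
    n_folds: int = 5,
):
    """Per-condition frequency-profile similarities with trial (transition)
    cross-validation.

    For each noise condition, the reconstructed DA and AA frequency
    profiles (peak-normalized, pooled over all of the condition's
    transitions) are compared with the condition's noise profile and with
    the clean-speech profile by regression R^2 (signed squared Pearson
    correlation, which tolerates the peak-normalization's arbitrary
    scale/offset); ``n_folds`` contiguous transition folds provide a
    per-fold spread. Clean references are
    computed from the clean original over the same analysis windows, so
    the comparison is content-matched at small trial counts. The
    DA-vs-clean number is the per-condition speech-masking index.

    Returns dict: condition -> {"r2_da_vs_noise", "r2_da_vs_clean",
    "r2_aa_vs_clean", "folds": per-fold triples}.
    """
    fr = recon.frame_rate
    noise_vals = np.clip(noisy_spec.values - clean_spec.values, 0.0, None)
    win_end = max(da[1], aa[1])
    trans, _ = _aligned_frames(schedule, fr, recon.n_frames, win_end, include_clean=False)
    by_cond = {}
    for i, cond in trans:
        by_cond.setdefault(cond, []).append(i)

    def window_profile(values, i, lo, hi):
        a, b = i + int(round(lo * fr)), i + int(round(hi * fr))
        return values[a:b].mean(axis=0)

    out = {}
    for cond, idx in sorted(by_cond.items()):
        if len(idx) < n_folds:
            raise ValueError(f"condition {cond}: {len(idx)} transitions < {n_folds} folds")
        def pooled_ref(values, lo, hi):
            prof = np.mean([window_profile(values, i, lo, hi) for i in idx], axis=0)
            mx = prof.max()
            return prof / mx if mx > 0 else prof

        # all references are content-matched to their analysis windows:
        # the DA-window noise reference legitimately includes the fading
        # previous background (compressed offsets decay slowly), exactly
        # as the stimulus did
        noise_ref_da = pooled_ref(noise_vals, *da)
        noise_ref_aa = pooled_ref(noise_vals, *aa)
        clean_ref_da = pooled_ref(clean_spec.values, *da)
        clean_ref_aa = pooled_ref(clean_spec.values, *aa)

        def group_profile(group, lo, hi):
            prof = np.mean([window_profile(recon.values, i, lo, hi) for i in group], axis=0)
            mx = prof.max()
            return prof / mx if mx > 0 else prof

        def quad(group):
            pda = group_profile(group, *da)
            paa = group_profile(group, *aa)
            return (
                regression_r2(pda, noise_ref_da),
                regression_r2(pda, clean_ref_da),
                regression_r2(paa, clean_ref_aa),
                regression_r2(paa, noise_ref_aa),
            )

        triples = np.array([quad(fold) for fold in np.array_split(np.array(idx), n_folds)])
        pooled = quad(idx)  # all transitions: the headline values
        out[cond] = {
            "r2_da_vs_noise": pooled[0],
            "r2_da_vs_clean": pooled[1],
            "r2_aa_vs_clean": pooled[2],
            "r2_aa_vs_noise": pooled[3],
            "folds": triples,
        }
    return out


def reconstruction_adaptation_interval(
    recon: Spectrogram,
    clean_spec: Spectrogram,
    schedule: TransitionSchedule,
    alpha: float = 0.01,
    window_s: float = 2.0,
    min_transitions: int = 10,
    grace_s: float = 0.25,
) -> float:
    """Duration (ms) of the reconstruction's post-transition deviation from
    the clean envelope.

    Per aligned frame, a paired t-test across transitions compares the
    reconstructed and clean broadband envelopes; the interval ends where
    the initial contiguous run of significant frames ends. The run may
    start anywhere within ``grace_s`` of the transition (the deviation
    builds up with the neural response latency); 0 if no frame within the
    grace period is significant. To
    isolate the post-transition divergence from any static reconstruction
    bias, both envelopes are baseline-matched per transition by
    subtracting their mean over the final quarter of the window.
    Degenerate ``alpha >= 1`` marks every frame significant and returns the
    full window (input-validity guard is the caller's job).
    """
    env_r = temporal_envelope(recon)
    env_c = temporal_envelope(clean_spec)
    trans, win = _aligned_frames(schedule, recon.frame_rate, recon.n_frames,
                                 window_s, include_clean=True)
    if len(trans) < min_transitions:
        raise ValueError(f"only {len(trans)} usable transitions (< {min_transitions})")
    if alpha >= 1.0:  # degenerate guard: every frame trivially significant
        return win * 1000.0 / recon.frame_rate
    idx = np.array([i for i, _ in trans])
    R = np.stack([env_r[i : i + win] for i in idx])  # K x win
    C = np.stack([env_c[i : i + win] for i in idx])
    b0 = 3 * win // 4
    R = R - R[:, b0:].mean(axis=1, keepdims=True)
    C = C - C[:, b0:].mean(axis=1, keepdims=True)
    pv = np.empty(win)
    for u in range(win):
        _, p = paired_t(R[:, u], C[:, u])
        pv[u] = 1.0 if np.isnan(p) else p
    sig = pv < alpha
    grace = int(round(grace_s * recon.frame_rate))
    start = np.nonzero(sig[: grace + 1])[0]
    if start.size == 0:
        return 0.0
    end = int(start[0])
    while end < win and sig[end]:
        end += 1
    return end * 1000.0 / recon.frame_rate
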