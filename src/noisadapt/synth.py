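"""Synthetic stimuli and simulated electrode populations.

The generator emulates the structure of a continuous speech-in-noise
listening task: a speech-like foreground (formant carriers with
syllabic-rate amplitude modulation and labelled phoneme-like events) is
mixed at a fixed SNR with one of three spectrally distinct background
noises — "jet" (high-frequency, fast modulation), "city" (spectrally
flat) and "bar" (low-frequency, slow modulation) — switching randomly
every 3 or 6 s among the four conditions (clean/jet/city/bar).

The simulated electrode population has known linear spectrotemporal
tuning, per-condition adaptive gain with a sub-second time constant, a
transient overshoot at condition transitions, speech-specific sites, and
additive Gaussian response noise. Per-condition adaptation strength is
linked to tuning by a_{i,c} = clip(kappa * overlap(tuning_i, profile_c)),
so that sites tuned to a noise's band adapt most to that noise — this
linkage is recorded in the ground truth so estimator recovery can be
checked against it.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as _sig

from ._design import lagged_design_causal as _lagged_design

__all__ = [
    "CONDITIONS",
    "TransitionSchedule",
    "StimulusConfig",
    "StimulusSet",
    "PopulationConfig",
    "PopulationGroundTruth",
    "generate_stimulus",
    "simulate_population",
    "simulate_responses",
]

CONDITIONS = ("clean", "jet", "city", "bar")

# synthesis bands of the three noises (Hz); these also define the canonical
# spectral profiles used by the tuning->adaptation linkage
NOISE_BANDS = {"jet": (2000.0, 5000.0), "city": (150.0, 5400.0), "bar": (100.0, 700.0)}
NOISE_AM_HZ = {"jet": 16.0, "city": 0.0, "bar": 2.5}


# ---------------------------------------------------------------------------
# transition schedule
# ---------------------------------------------------------------------------

@dataclass
class TransitionSchedule:
    """Ordered background-condition blocks.

    ``onsets[0] == 0``; consecutive blocks always differ in condition, so
    every block onset after the first is a genuine transition.
    """

    onsets: np.ndarray  # seconds, strictly increasing, first = 0
    conditions: list  # same length, values in CONDITIONS
    total_duration_s: float

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size == 0 or self.onsets[0] != 0:
            raise ValueError("schedule must start at t=0")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.conditions) != self.onsets.size:
            raise ValueError("conditions/onsets length mismatch")
        for a, b in zip(self.conditions, self.conditions[1:]):
            if a == b:
                raise ValueError("consecutive blocks must differ in condition")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")

    @property
    def n_blocks(self) -> int:
        return self.onsets.size

    def block_bounds(self):
        """Yield (onset_s, offset_s, condition) per block, half-open."""
        offs = np.append(self.onsets[1:], self.total_duration_s)
        for t0, t1, c in zip(self.onsets, offs, self.conditions):
            yield float(t0), float(t1), c

    def transitions(self):
        """(time_s, new_condition) for every block onset after the first."""
        return [(float(t), c) for t, c in zip(self.onsets[1:], self.conditions[1:])]

    def condition_at(self, t: float) -> str:
        i = int(np.searchsorted(self.onsets, t, side="right")) - 1
        return self.conditions[max(i, 0)]

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("onset_s\tcondition\n")
            for t, c in zip(self.onsets, self.conditions):
                fh.write(f"{t:.6f}\t{c}\n")

    @classmethod
    def from_tsv(cls, path, total_duration_s):
        onsets, conds = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                t, c = line.rstrip("\n").split("\t")
                onsets.append(float(t))
                conds.append(c)
        return cls(np.array(onsets), conds, total_duration_s)


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

@dataclass
class StimulusConfig:
    duration_s: float = 60.0
    fs: float = 11025.0
    block_durations_s: tuple = (3.0, 6.0)
    block_duration_probs: tuple | None = None  # uniform over the set if None
    snr_db: float = 6.0
    speech_in_noise: bool = True  # False: foreground gated off in noise blocks
    n_phoneme_templates: int = 25
    phoneme_dur_range_s: tuple = (0.08, 0.18)
    syllable_gap_s: tuple = (0.05, 0.12)
    word_gap_s: float = 0.25
    sentence_pause_s: float = 0.8  # every ~5 words, like narrated speech
    words_per_sentence: int = 5
    noise_recording_s: float = 60.0


@dataclass
class StimulusSet:
    clean_wave: np.ndarray
    mixed_wave: np.ndarray
    noise_only_wave: np.ndarray
    fs: float
    schedule: TransitionSchedule
    phonemes: list  # (onset_s, offset_s, label)
    snr_db: float

    def write(self, outdir):
        """Write WAVs + schedule/phoneme TSVs into ``outdir``."""
        import os
        from scipy.io import wavfile

        os.makedirs(outdir, exist_ok=True)
        for name, w in [
            ("clean.wav", self.clean_wave),
            ("mixed.wav", self.mixed_wave),
            ("noise_only.wav", self.noise_only_wave),
        ]:
            wavfile.write(os.path.join(outdir, name), int(self.fs), w.astype(np.float32))
        self.schedule.to_tsv(os.path.join(outdir, "schedule.tsv"))
        with open(os.path.join(outdir, "phonemes.tsv"), "w") as fh:
            fh.write("onset_s\toffset_s\tlabel\n")
            for t0, t1, lab in self.phonemes:
                fh.write(f"{t0:.6f}\t{t1:.6f}\t{lab}\n")


def _make_schedule(cfg: StimulusConfig, rng: np.random.Generator) -> TransitionSchedule:
    durs = np.asarray(cfg.block_durations_s, dtype=float)
    probs = cfg.block_duration_probs
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
    if cfg.duration_s < durs.min():
        raise ValueError("duration too short for a single block")
    onsets, conds = [], []
    t = 0.0
    prev = None
    while True:
        feasible = durs[durs <= cfg.duration_s - t + 1e-9]
        if feasible.size == 0:
            break
        if probs is None:
            d = float(rng.choice(durs))
        else:
            d = float(rng.choice(durs, p=probs))
        if d > cfg.duration_s - t + 1e-9:
            d = float(rng.choice(feasible))
        choices = [c for c in CONDITIONS if c != prev]
        c = str(rng.choice(choices))
        onsets.append(t)
        conds.append(c)
        prev = c
        t += d
    return TransitionSchedule(np.array(onsets), conds, total_duration_s=t)


def _phoneme_templates(n: int, rng: np.random.Generator):
    """Distinct spectral templates: 2-3 formant frequencies + amplitudes,
    about a third with a fricative-like high-frequency noise component
    (so the foreground, like natural speech, carries energy up to the top
    of the hearing band)."""
    templates = []
    for i in range(n):
        # realistic spectral balance: strong F1 (low), weaker F2/F3 —
        # narrated speech concentrates power below ~1 kHz
        freqs = [np.exp(rng.uniform(np.log(160.0), np.log(700.0)))]
        amps = [1.0 * rng.uniform(0.85, 1.15)]
        freqs.append(np.exp(rng.uniform(np.log(800.0), np.log(2200.0))))
        amps.append(0.35 * rng.uniform(0.8, 1.2))
        if rng.random() < 0.7:
            freqs.append(np.exp(rng.uniform(np.log(2300.0), np.log(3300.0))))
            amps.append(0.18 * rng.uniform(0.8, 1.2))
        frication = float(rng.uniform(0.2, 0.4)) if rng.random() < 0.3 else 0.0
        templates.append((f"ph{i:02d}", np.array(freqs), np.array(amps), frication))
    return templates


def _speech_surrogate(cfg: StimulusConfig, total_s: float, rng: np.random.Generator):
    """Formant-carrier foreground with labelled phoneme-like events.

    Phonemes are grouped into syllables separated by short gaps, words by
    longer gaps and sentences by pauses, producing amplitude modulation in
    the 2-6 Hz syllabic range and the ~50% temporal duty cycle of
    narrated speech.
    """
    fs = cfg.fs
    n = int(round(total_s * fs))
    wave = np.zeros(n)
    templates = _phoneme_templates(cfg.n_phoneme_templates, rng)
    sos_fric = _sig.butter(4, [2500.0, min(5200.0, 0.49 * fs)], btype="bandpass",
                           fs=fs, output="sos")
    phonemes = []
    t = float(rng.uniform(0.01, 0.05))
    syllable_len = int(rng.integers(1, 4))
    in_syllable = 0
    syllables_in_word = 0
    words_in_sentence = 0
    while True:
        dur = float(rng.uniform(*cfg.phoneme_dur_range_s))
        if t + dur > total_s:
            break
        lab, freqs, amps, frication = templates[int(rng.integers(len(templates)))]
        i0, i1 = int(round(t * fs)), int(round((t + dur) * fs))
        seg_t = np.arange(i1 - i0) / fs
        ramp = min(0.012, dur / 4)
        env = np.minimum(1.0, np.minimum(seg_t / ramp, (dur - seg_t) / ramp))
        env = np.clip(env, 0.0, 1.0)
        seg = np.zeros(i1 - i0)
        for f0, a in zip(freqs, amps):
            drift = f0 * rng.uniform(-0.05, 0.05)
            inst_f = f0 + drift * seg_t / dur  # slow formant glide
            phase = 2 * np.pi * np.cumsum(inst_f) / fs + rng.uniform(0, 2 * np.pi)
            seg += a * np.sin(phase)
        if frication:
            burst = _sig.sosfilt(sos_fric, rng.standard_normal(i1 - i0))
            seg += frication * burst / (np.std(burst) + 1e-12)
        wave[i0:i1] += seg * env
        phonemes.append((t, t + dur, lab))
        t += dur
        in_syllable += 1
        if in_syllable >= syllable_len:
            in_syllable = 0
            syllable_len = int(rng.integers(1, 4))
            syllables_in_word += 1
            if syllables_in_word >= 3:
                syllables_in_word = 0
                words_in_sentence += 1
                if words_in_sentence >= cfg.words_per_sentence:
                    words_in_sentence = 0
                    t += cfg.sentence_pause_s
                else:
                    t += cfg.word_gap_s
            else:
                t += float(rng.uniform(*cfg.syllable_gap_s))
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave *= 0.1 / rms
    return wave, phonemes


def _noise_recording(cond: str, dur_s: float, fs: float, rng: np.random.Generator):
    """Minute-long seeded noise recording for one condition."""
    n = int(round(dur_s * fs))
    x = rng.standard_normal(n)
    lo, hi = NOISE_BANDS[cond]
    sos = _sig.butter(4, [lo, min(hi, 0.49 * fs)], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfilt(sos, x)
    if cond == "city":
        # mild pink tilt (power ~ f^-0.5): spectrally broad and much
        # flatter than the other noises, without being so featureless that
        # profile comparisons against it degenerate
        X = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        H = np.ones_like(f)
        m = f > lo
        H[m] = (lo / f[m]) ** 0.25
        x = np.fft.irfft(X * H, n)
    am = NOISE_AM_HZ[cond]
    if am > 0:
        # stochastic amplitude modulation concentrated around `am` Hz
        mod = rng.standard_normal(n)
        sos_m = _sig.butter(2, am, btype="lowpass", fs=fs, output="sos")
        mod = _sig.sosfilt(sos_m, mod)
        mod = mod / (np.std(mod) + 1e-12)
        x = x * (1.0 + 0.6 * np.tanh(mod))
    rms = np.sqrt(np.mean(x**2))
    return x / (rms + 1e-12)


def generate_stimulus(config: StimulusConfig, seed: int) -> StimulusSet:
    """Generate clean, noise-only, and mixed waveforms plus schedule and
    phoneme labels. Within each non-clean block the noise segment is cut at
    a random offset from the condition's minute-long recording and scaled so
    the block's speech-to-noise power ratio equals ``config.snr_db``.
    """
    if not np.isfinite(config.snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    schedule = _make_schedule(config, rng)
    total = schedule.total_duration_s
    fs = config.fs
    n = int(round(total * fs))

    speech, phonemes = _speech_surrogate(config, total, rng)
    speech = speech[:n]
    speech_power_global = np.mean(speech**2)

    recordings = {c: _noise_recording(c, config.noise_recording_s, fs, rng)
                  for c in CONDITIONS if c != "clean"}

    clean = speech.copy()
    noise_only = np.zeros(n)
    snr_lin = 10.0 ** (config.snr_db / 10.0)
    for t0, t1, cond in schedule.block_bounds():
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
        if cond == "clean":
            continue
        if not config.speech_in_noise:
            clean[i0:i1] = 0.0  # foreground gated off during noise blocks
        rec = recordings[cond]
        max_off = rec.size - (i1 - i0)
        if max_off <= 0:
            raise ValueError("noise recording shorter than block")
        off = int(rng.integers(0, max_off))
        seg = rec[off : off + (i1 - i0)].copy()
        # raised-cosine edge ramps: un-ramped splices click, and the
        # compressive cochlear stage amplifies the broadband splatter
        nr = min(int(0.02 * fs), seg.size // 4)
        if nr > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            seg[:nr] *= ramp
            seg[-nr:] *= ramp[::-1]
        p_speech = np.mean(clean[i0:i1] ** 2)
        ref_power = p_speech if (config.speech_in_noise and p_speech > 0) else speech_power_global
        p_seg = np.mean(seg**2)
        gain = np.sqrt(ref_power / (p_seg * snr_lin))
        noise_only[i0:i1] = gain * seg

    if not config.speech_in_noise:
        phonemes = [
            (a, b, lab) for a, b, lab in phonemes
            if schedule.condition_at(a) == "clean"
        ]
    mixed = clean + noise_only
    return StimulusSet(clean, mixed, noise_only, fs, schedule, phonemes, config.snr_db)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    n_sites: int = 60
    n_bands: int = 13
    freq_lo: float = 180.0
    freq_hi: float = 5400.0
    n_lags: int = 26  # 0..250 ms at 10 ms resolution
    frame_rate: float = 100.0
    latency_range_ms: tuple = (40.0, 110.0)
    speech_latency_shift_ms: float = 40.0  # extra latency for speech-specific sites
    rate_range_hz: tuple = (3.0, 10.0)
    temporal_sigma_ms: tuple = (50.0, 70.0)
    spectral_sigma_oct: tuple = (0.3, 0.6)
    frac_speech_specific: float = 0.3
    frac_nonadaptive: float = 0.15
    # adaptation strength a = clip(kappa * q) where q is the fraction of
    # the site's spectral drive contributed by the noise (input-driven
    # depression): q = <tuning, noise> / (<tuning, noise> + <tuning, speech>)
    kappa: float = 1.3
    a_clean_speech: tuple = (0.5, 0.9)  # a_clean for speech-specific sites
    a_clean_other: tuple = (0.0, 0.1)
    # non-adaptive sites respond mainly to speech (higher-order, long-
    # latency sites); their noise drive is scaled down by this factor
    nonadaptive_noise_gain: float = 0.25
    tau_range_s: tuple = (0.3, 0.5)
    transient_gain_range: tuple = (0.6, 1.4)
    # transient overshoot of the noise-feature response at a background
    # switch: the noise gain momentarily rises to ~(1 + onset_boost * a)
    # before adaptation takes hold ("momentary response to noise features")
    onset_boost: float = 1.5
    transient_rise_s: float = 0.05
    transient_decay_s: float = 0.3
    # divisive masking of the speech response by the unadapted noise: at a
    # noise onset the population speech drive is suppressed by
    # min(0.95, masking_strength * mean(a_c)), recovering with the
    # adaptation time constant as the noise response is suppressed; a
    # non-adapting population (a = 0) exerts no masking
    masking_strength: float = 1.7
    # fraction of a noise stream's accumulated adaptation released when
    # the scene changes (change-detection reset): the tail of a noise that
    # just ended is briefly re-represented before fading
    change_reset: float = 0.75
    speech_gain_range: tuple = (0.8, 1.6)
    noise_sd: float = 0.3


def noise_profile(cond: str, freqs: np.ndarray) -> np.ndarray:
    """Canonical unit-norm spectral profile of a background condition on a
    given frequency axis (matches the synthesis bands)."""
    lo, hi = NOISE_BANDS[cond]
    logf = np.log(freqs)
    prof = np.where((freqs >= lo) & (freqs <= hi), 1.0, 0.0)
    # soft band edges: half-octave cosine rolloff
    roll = 0.5 * np.log(2)
    prof = np.maximum(prof, np.exp(-((logf - np.log(lo)) ** 2) / (2 * roll**2)) * (freqs < lo))
    prof = np.maximum(prof, np.exp(-((logf - np.log(hi)) ** 2) / (2 * roll**2)) * (freqs > hi))
    return prof / np.linalg.norm(prof)


def speech_profile(freqs: np.ndarray) -> np.ndarray:
    """Canonical unit-norm spectral profile of the speech-like foreground:
    a broad low/mid-frequency bump (formant region)."""
    prof = np.exp(-((np.log2(freqs) - np.log2(500.0)) ** 2) / (2 * 1.3**2))
    return prof / np.linalg.norm(prof)


@dataclass
class PopulationGroundTruth:
    strf_true: np.ndarray  # n_sites x n_lags x n_bands
    a: np.ndarray  # n_sites x 4, condition order = CONDITIONS
    noise_gain: np.ndarray  # per-site gain on the noise drive
    tau_s: np.ndarray
    transient_gain: np.ndarray
    speech_gain: np.ndarray  # 0 for non-speech-specific sites
    noise_sd: np.ndarray
    best_freq_hz: np.ndarray
    latency_ms: np.ndarray
    rate_hz: np.ndarray
    freq_axis: np.ndarray
    lag_axis_ms: np.ndarray
    is_speech_specific: np.ndarray
    seed: int
    config: PopulationConfig = field(repr=False)

    @property
    def n_sites(self) -> int:
        return self.strf_true.shape[0]

    def sidecar(self) -> dict:
        """JSON-serializable ground-truth record (per-site parameters,
        seed, config echo); the kernels themselves are reconstructible from
        (config, seed)."""
        return {
            "seed": int(self.seed),
            "config": asdict(self.config),
            "condition_order": list(CONDITIONS),
            "sites": [
                {
                    "a": [float(v) for v in self.a[i]],
                    "noise_gain": float(self.noise_gain[i]),
                    "tau_s": float(self.tau_s[i]),
                    "transient_gain": float(self.transient_gain[i]),
                    "speech_gain": float(self.speech_gain[i]),
                    "noise_sd": float(self.noise_sd[i]),
                    "best_freq_hz": float(self.best_freq_hz[i]),
                    "latency_ms": float(self.latency_ms[i]),
                    "rate_hz": float(self.rate_hz[i]),
                    "is_speech_specific": bool(self.is_speech_specific[i]),
                }
                for i in range(self.n_sites)
            ],
        }

    def write_sidecar(self, path):
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=1)


def concat_populations(pops) -> PopulationGroundTruth:
    """Pool several simulated populations (e.g. per-subject draws) into
    one ground-truth record; array fields are concatenated."""
    pops = list(pops)
    first = pops[0]
    import dataclasses as _dc

    kw = {}
    for f in _dc.fields(PopulationGroundTruth):
        vals = [getattr(p, f.name) for p in pops]
        if f.name in ("freq_axis", "lag_axis_ms", "seed", "config"):
            kw[f.name] = vals[0]
        else:
            kw[f.name] = np.concatenate(vals, axis=0)
    return PopulationGroundTruth(**kw)


def simulate_population(config: PopulationConfig, seed: int) -> PopulationGroundTruth:
    """Draw a population with linked tuning and adaptation.

    Each site's kernel is a spectral Gaussian (log axis) times a Gaussian-
    windowed cosine in lag (setting its preferred temporal modulation rate).
    Adaptation strength per noise condition follows
    ``a = clip(kappa * cos_sim(tuning, noise_profile), 0, 1)``; a configured
    fraction of sites is non-adaptive (a = 0 everywhere), and
    speech-specific sites additionally adapt to the clean condition and
    carry longer response latencies.
    """
    if config.n_sites < 1:
        raise ValueError("population must be non-empty")
    if not (0 <= config.frac_speech_specific <= 1 and 0 <= config.frac_nonadaptive <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ns = config.n_sites
    freqs = np.geomspace(config.freq_lo, config.freq_hi, config.n_bands)
    lags_ms = np.arange(config.n_lags) * 1000.0 / config.frame_rate
    logf = np.log2(freqs)

    # stratified log-spaced best frequencies (jittered grid): guarantees
    # population coverage of the whole hearing band at any size
    grid = np.linspace(np.log(config.freq_lo * 1.2), np.log(config.freq_hi / 1.2), ns)
    step = (grid[-1] - grid[0]) / max(ns - 1, 1)
    bf = np.exp(rng.permutation(grid) + rng.uniform(-0.5, 0.5, ns) * step)
    lat = rng.uniform(*config.latency_range_ms, ns)
    rate = rng.uniform(*config.rate_range_hz, ns)
    sig_t = rng.uniform(*config.temporal_sigma_ms, ns)
    sig_f = rng.uniform(*config.spectral_sigma_oct, ns)

    n_spec = int(round(config.frac_speech_specific * ns))
    n_nonad = int(round(config.frac_nonadaptive * ns))
    order = rng.permutation(ns)
    is_spec = np.zeros(ns, dtype=bool)
    is_spec[order[:n_spec]] = True
    # non-adaptive sites drawn from the end of the permutation so the two
    # groups only overlap when the fractions require it
    nonad = np.zeros(ns, dtype=bool)
    nonad[order[ns - n_nonad :] if n_nonad else []] = True
    lat = lat + is_spec * config.speech_latency_shift_ms

    kernels = np.zeros((ns, config.n_lags, config.n_bands))
    for i in range(ns):
        gf = np.exp(-((logf - np.log2(bf[i])) ** 2) / (2 * sig_f[i] ** 2))
        gt = np.exp(-((lags_ms - lat[i]) ** 2) / (2 * sig_t[i] ** 2))
        gt = gt * np.cos(2 * np.pi * rate[i] * (lags_ms - lat[i]) / 1000.0)
        kernels[i] = np.outer(gt, gf)

    profiles = {c: noise_profile(c, freqs) for c in CONDITIONS if c != "clean"}
    sp_prof = speech_profile(freqs)
    a = np.zeros((ns, len(CONDITIONS)))
    for i in range(ns):
        tuning = np.clip(kernels[i], 0, None).sum(axis=0)
        drive_speech = float(tuning @ sp_prof)
        for j, c in enumerate(CONDITIONS):
            if c == "clean":
                lo, hi = (config.a_clean_speech if is_spec[i] else config.a_clean_other)
                a[i, j] = rng.uniform(lo, hi)
            else:
                drive_noise = float(tuning @ profiles[c])
                q = drive_noise / (drive_noise + drive_speech + 1e-12)
                a[i, j] = np.clip(config.kappa * q, 0.0, 1.0)
    a[nonad] = 0.0
    noise_gain = np.where(nonad, config.nonadaptive_noise_gain, 1.0)

    return PopulationGroundTruth(
        strf_true=kernels,
        a=a,
        noise_gain=noise_gain,
        tau_s=rng.uniform(*config.tau_range_s, ns),
        transient_gain=rng.uniform(*config.transient_gain_range, ns),
        speech_gain=np.where(is_spec, rng.uniform(*config.speech_gain_range, ns), 0.0),
        noise_sd=np.full(ns, float(config.noise_sd)),
        best_freq_hz=bf,
        latency_ms=lat,
        rate_hz=rate,
        freq_axis=freqs,
        lag_axis_ms=lags_ms,
        is_speech_specific=is_spec,
        seed=seed,
        config=config,
    )


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def _alpha_kernel(frame_rate: float, rise_s: float = 0.05, decay_s: float = 0.3) -> np.ndarray:
    """Difference-of-exponentials transient kernel, peak-normalized to 1,
    truncated below 1% of peak (support < 1 s for the default shape)."""
    t = np.arange(0, 1.5, 1.0 / frame_rate)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    k /= k.max()
    peak = int(np.argmax(k))
    tail = np.nonzero(k[peak:] < 0.01)[0]
    end = peak + int(tail[0]) if tail.size else k.size
    return k[:end]


def simulate_responses(
    stim_spec,
    clean_spec,
    pop: PopulationGroundTruth,
    schedule: TransitionSchedule,
    seed: int,
    adaptation_on: bool = True,
    noise_specs: dict | None = None,
):
    """Simulate the population's high-gamma-like envelope responses.

    ``noise_specs`` optionally resolves the background into per-condition
    noise spectrograms (condition -> Spectrogram of that noise's
    contribution over the whole recording). With it, each noise stream is
    gated by its own adaptation state, which is held between that
    condition's blocks — so the acoustic tail of a noise that just ended
    is still suppressed by the adaptation it induced. Without it, the
    pooled noise component clip(stim - clean) is gated by the current
    block's condition.

    Site i:
      r_i(t) = (1 - m_i(t)) rect[K_i * S_speech](t)
             + (1 - d_{i,c}(t) + boost_i(t)) rect[K_i * S_noise](t)
             + g_i speech_env(t) (1 - d_speech,i(t))
             + transient_i(t) + eps_i(t)

    with m(t) = min(0.95, masking_strength * abar_c) (1 - growth(t)) in
    noise blocks (0 in clean blocks): the unadapted noise divisively masks
    the speech response population-wide (divisive gain normalization), and
    adaptation releases it; boost(t) = onset_boost * abar_c * alpha(t) is
    the population-wide transient noise-gain overshoot at each switch
    (abar_c is the population-mean adaptation strength for the incoming
    condition). Site-specific diversity lives in d_{i,c}.

    where d_{i,c}(t) = a_{i,c} (1 - exp(-(t - t_k)/tau_i)) restarts at every
    transition t_k into condition c. The speech-specific term sits at its
    adapted steady state (1 - a_{i,clean}) throughout — matching a long
    clean training recording — except after a transition INTO clean, where
    it resets to full gain and re-adapts: the recovery of speech-selective
    responses from their noise-adapted state when the noise stops. When ``clean_spec`` is None the stimulus is treated
    as noise-alone: the foreground terms vanish and d is held at 0, so noise
    responses are sustained. Drives are scaled per site to unit RMS of the
    (speech, or noise-alone) drive so response units are comparable across
    sites. ``adaptation_on=False`` freezes d at 0 and removes transients
    (equivalent to a = 0 everywhere) without changing any other draw.

    Returns a ``preprocess.NeuralRecording`` at the model frame rate.
    """
    from .preprocess import NeuralRecording

    rng = np.random.default_rng(seed)
    fr = pop.config.frame_rate
    noise_only = clean_spec is None
    base = stim_spec if noise_only else clean_spec
    if abs(stim_spec.frame_rate - fr) > 1e-9:
        raise ValueError("spectrogram frame rate does not match population model")
    if not noise_only:
        if clean_spec.n_frames != stim_spec.n_frames:
            raise ValueError("mismatched time axes between stimulus spectrograms")
        if clean_spec.n_bands != stim_spec.n_bands:
            raise ValueError("mismatched frequency axes")
    if stim_spec.n_bands != pop.strf_true.shape[2]:
        raise ValueError("spectrogram bands do not match population kernels")
    T = stim_spec.n_frames
    n_lags = pop.strf_true.shape[1]
    ns = pop.n_sites
    K = pop.strf_true.reshape(ns, -1).T  # (lags*bands) x sites

    if noise_only:
        speech_vals = np.zeros_like(stim_spec.values)
        streams = [(None, stim_spec.values)]
    else:
        speech_vals = clean_spec.values
        if noise_specs is not None:
            streams = [(c, s.values) for c, s in sorted(noise_specs.items())]
        else:
            streams = [(None, np.clip(stim_spec.values - clean_spec.values, 0.0, None))]

    drive_speech = np.clip(_lagged_design(speech_vals, n_lags) @ K, 0.0, None)
    noise_drives = []
    for c, vals in streams:
        dv = np.clip(_lagged_design(vals, n_lags) @ K, 0.0, None)
        noise_drives.append((c, dv * pop.noise_gain[None, :]))
    # one population-level scale (mean site RMS of the foreground drive):
    # keeps natural cross-site gain differences while putting responses in
    # comparable units
    ref = sum(dv for _, dv in noise_drives) if noise_only else drive_speech
    scale = 1.0 / (np.mean(np.sqrt(np.mean(ref**2, axis=0))) + 1e-12)
    drive_speech *= scale
    noise_drives = [(c, dv * scale) for c, dv in noise_drives]

    t_axis = np.arange(T) / fr
    cond_idx = {c: j for j, c in enumerate(CONDITIONS)}

    # speech-term gain and the divisive masking of the speech drive by the
    # unadapted noise
    d_speech = np.zeros((T, ns))
    mask_t = np.zeros((T, ns))
    if adaptation_on and not noise_only:
        a_clean = pop.a[:, cond_idx["clean"]]
        d_speech[:] = a_clean[None, :]  # adapted steady state by default
        m_str = pop.config.masking_strength
        for t0, t1, cond in schedule.block_bounds():
            m = (t_axis >= t0) & (t_axis < t1)
            if not m.any():
                continue
            u = t_axis[m] - t0
            growth = 1.0 - np.exp(-np.outer(u, 1.0 / pop.tau_s))
            if cond == "clean":
                # recovery + re-adaptation after the noise stops
                d_speech[m] = a_clean[None, :] * growth
            else:
                # population-wide divisive masking released by adaptation;
                # scales with how strongly the population adapts to this
                # noise, so a non-adapting population exerts no masking
                a_bar = float(pop.a[:, cond_idx[cond]].mean())
                mask_t[m] = min(0.95, m_str * a_bar) * (1.0 - growth)

    def _stream_gain(stream_cond):
        """Per-frame noise gain (1 - d + boost) for one noise stream.

        For a condition-resolved stream, adaptation grows inside that
        condition's blocks and the reached level is HELD between them, so
        the acoustic tail of a just-ended noise is still gated by the
        adaptation it induced; for the unresolved (pooled) stream the gain
        follows the current block's condition, restarting at transitions.
        """
        gain = np.ones((T, ns))
        if not adaptation_on or noise_only:
            return gain
        ak = _alpha_kernel(fr, pop.config.transient_rise_s, pop.config.transient_decay_s)
        boost = pop.config.onset_boost
        held = np.zeros(ns)
        for t0, t1, cond in schedule.block_bounds():
            m = (t_axis >= t0) & (t_axis < t1)
            if not m.any():
                continue
            u = t_axis[m] - t0
            if stream_cond is None:
                a_c = pop.a[:, cond_idx[cond]]
                growth = 1.0 - np.exp(-np.outer(u, 1.0 / pop.tau_s))
                gain[m] = 1.0 - a_c[None, :] * growth
            elif cond == stream_cond:
                a_c = pop.a[:, cond_idx[cond]]
                growth = 1.0 - np.exp(-np.outer(u, 1.0 / pop.tau_s))
                gain[m] = 1.0 - a_c[None, :] * growth
                held = a_c * (1.0 - np.exp(-(t1 - t0) / pop.tau_s))
            else:
                # scene change partially resets the held adaptation
                held = held * (1.0 - pop.config.change_reset)
                gain[m] = 1.0 - held[None, :]
        # transient population-wide overshoot at switches into the stream's
        # condition (every switch for the pooled stream)
        for t_k, cond in schedule.transitions():
            if stream_cond is not None and cond != stream_cond:
                continue
            i0 = int(round(t_k * fr))
            if i0 >= T or cond == "clean":
                continue
            seg = min(ak.size, T - i0)
            amp = boost * float(pop.a[:, cond_idx[cond]].mean())
            gain[i0 : i0 + seg] += amp * ak[:seg, None]
        return gain

    if noise_only:
        speech_env = np.zeros(T)
    else:
        speech_env = clean_spec.values.mean(axis=1)
        rms = np.sqrt(np.mean(speech_env**2))
        if rms > 0:
            speech_env = speech_env / rms

    resp = (1.0 - mask_t) * drive_speech
    for c, dv in noise_drives:
        resp += _stream_gain(c) * dv
    # the speech-specific drive is a speech-driven response too: masked by
    # the fresh noise like the spectrotemporal speech drive
    resp += (pop.speech_gain[None, :] * speech_env[:, None]
             * (1.0 - d_speech) * (1.0 - mask_t))

    if adaptation_on and not noise_only:
        # additive overshoot at transitions into clean: recovery of the
        # (noise-adapted) speech-selective response when the noise stops;
        # transients at noise transitions come from the noise-gain boost
        ak = _alpha_kernel(fr, pop.config.transient_rise_s, pop.config.transient_decay_s)
        for t_k, cond in schedule.transitions():
            if cond != "clean":
                continue
            i0 = int(round(t_k * fr))
            if i0 >= T:
                continue
            seg = min(ak.size, T - i0)
            amp = pop.transient_gain * pop.a[:, cond_idx["clean"]]
            resp[i0 : i0 + seg] += np.outer(ak[:seg], amp)

    resp += rng.standard_normal((T, ns)) * pop.noise_sd[None, :]
    return NeuralRecording(
        response=resp.T,
        fs=fr,
        electrode_ids=[f"e{i:03d}" for i in range(ns)],
    )
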