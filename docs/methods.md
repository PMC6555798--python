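# Methods

This note documents the models and procedures implemented in `noisadapt`,
the assumptions behind them, the parameters that matter, and what the
synthetic study conditions do and do not establish.

## 1. Auditory spectrogram

The time–frequency frontend mimics peripheral auditory processing:

1. a bank of `n_filters = 128` gammatone (constant-Q, asymmetric) IIR
   filters with centre frequencies log-spaced over 180 Hz – 5.4 kHz
   (half-octave margins at 11 025 Hz sampling);
2. compressive nonlinearity — signed cube root by default, exponent
   configurable;
3. first-order difference across adjacent bands (lateral inhibition),
   half-wave rectified;
4. envelope extraction by rectified mean over each 10-ms frame
   (`frame_rate = 100` Hz). Frame *t* covers `[t/fr, (t+1)/fr)`,
   half-open, 0-based; the output length is `floor(n_samples·fr/fs)`.

The 128 bands are reduced to 13 by averaging within equal-width bins on
the log-frequency axis (flat inputs stay flat; mean power per frame is
conserved).

Two consequences of the compressive stage matter downstream and are
worth stating explicitly. First, a pure tone's profile peaks at (or
within one band of) the nearest centre frequency despite the spectral
differencing. Second, *acoustic offsets decay slowly in the compressed
domain*: a sound that ends at `t0` remains visible in the spectrogram
for 100–200 ms, because the cube root expands small amplitudes. The
early post-transition window of any analysis therefore legitimately
contains the fading previous background; the analysis code
content-matches its reference profiles to the same windows for this
reason.

## 2. Synthetic stimulus

The foreground is a speech surrogate: phoneme-like events drawn from 25
spectral templates (strong low-frequency "F1" 160–700 Hz, weaker F2/F3;
~30% of templates add a fricative-like 2.5–5.2 kHz noise burst), each
80–180 ms with raised-cosine edges and slow formant glides. Events are
grouped into syllables, words and sentences with gaps (60–120 ms, 250 ms,
800 ms), producing syllabic-rate (2–6 Hz) amplitude modulation and a
~60% temporal duty cycle, like narrated speech. The surrogate's average
spectrum is low/mid dominated with a modest high-frequency shelf.

Three backgrounds with deliberately contrasting spectra: **jet**
(2–5 kHz bandpass, fast ~16 Hz stochastic amplitude modulation), **city**
(broadband with a mild pink tilt, power ∝ f^−0.5 — spectrally much
flatter than the others without being degenerate), **bar** (100–700 Hz,
slow ~2.5 Hz modulation). Each condition has a one-minute seeded
recording; each block takes a random offset into it, with 20-ms
crossfades (un-ramped splices click, and the compressive frontend
amplifies the splatter).

The schedule draws 3-s or 6-s blocks, conditions uniform among the three
not currently playing (a transition always changes the condition). Noise
is scaled per block so the realized speech-to-noise power ratio is
6 ± 0.5 dB. Clean blocks add nothing. With the foreground gated off in
noise blocks (`speech_in_noise=False`) the same machinery produces a
speech/nonspeech battery for the speech-specificity analysis.

## 3. Simulated electrode population

Each site has a planted spectrotemporal kernel — a log-axis spectral
Gaussian (σ 0.3–0.6 octaves) times a Gaussian-windowed cosine in lag
(latency 40–110 ms, +40 ms for speech-specific sites; rate 3–10 Hz;
σ_t 50–70 ms). Best frequencies are stratified (jittered log grid) so any
population size covers the hearing band. 30% of sites are
speech-specific (extra drive following the clean-speech envelope), 15%
non-adaptive (their noise drive is also reduced ×0.25 — sites without
adaptive noise responses sit higher in the pathway and respond mainly to
speech, consistent with their long latencies).

**Tuning–adaptation linkage.** Adaptation strength for noise condition
*c* is `a = clip(κ · q, 0, 1)` with `q = ⟨T,N_c⟩ / (⟨T,N_c⟩ + ⟨T,S⟩)` —
the fraction of the site's spectral drive contributed by that noise
(input-driven depression), where `T` is the site's positive spectral
tuning, `N_c` the canonical noise profile and `S` a canonical speech
profile; κ = 1.3. High-frequency sites therefore adapt strongly to jet,
low-frequency sites to bar, and the flat city noise produces a weaker,
less linear dependence. Speech-specific sites draw `a_clean` ∈ 0.5–0.9
(others ≈ 0), so adaptation *to the clean condition* marks
speech-selective sites, as in the recordings.

**Response model.** With per-condition noise spectrograms `S_c` (the
pipeline computes them as `spec(clean + noise_c) − spec(clean)`):

```
r_i(t) = (1 − m(t)) · rect[K_i ⋆ S_speech](t)
       + Σ_c g_{i,c}(t) · rect[K_i ⋆ S_c](t)
       + g_i · env_speech(t) · (1 − d_speech,i(t)) · (1 − m(t))
       + transient_i(t) + ε_i(t)
```

* `g_{i,c}(t) = 1 − d_{i,c}(t) + boost_c(t)`. Within a block of
  condition *c*, `d_{i,c}(t) = a_{i,c}(1 − e^{−u/τ_i})` grows from the
  block onset (τ ~ 0.3–0.5 s). Between that condition's blocks the
  reached level is **held** — the acoustic tail of a noise that just
  ended is still gated by the adaptation it induced — except that each
  scene change releases 75% of the held adaptation (change-detection
  reset), so the old background is briefly re-represented before fading.
* `boost_c(t)` is a population-wide transient overshoot of the
  noise-feature response at each switch: an α-kernel (50 ms rise, 300 ms
  decay) scaled by `onset_boost · mean(a_c)` (default 1.5) — the
  "momentary response to the fresh noise" before adaptation takes hold.
* `m(t) = min(0.95, masking_strength · mean(a_c)) (1 − e^{−u/τ})` is a
  population-wide divisive masking of the *speech* response by the
  unadapted noise, released as adaptation suppresses it
  (`masking_strength = 1.7`, i.e. ~0.8–0.95 at a switch). A non-adapting
  population (a = 0) exerts no masking, so the a = 0 null is exactly the
  static linear drive plus noise.
* The speech-specific term sits at its adapted steady state
  `(1 − a_clean)` everywhere — matching a long clean training
  recording — except after a transition *into clean*, where it resets to
  full gain and re-adapts (recovery of speech-selective responses when
  the noise stops); an additive α-kernel transient at clean transitions
  models the same recovery overshoot.
* ε is white Gaussian, σ = 0.3 in units where the population-mean RMS of
  the speech drive is 1 (one common scale, preserving natural
  cross-site gain differences).

Two modelling choices deserve emphasis because they were forced by the
linear-decoding analyses. A *site-generic additive* transient at every
transition decodes into a population-specific broadband artifact (it
lies outside the response manifold spanned by stimulus-driven activity),
so the noise-transition transient is implemented as a gain on the noise
drive instead. Likewise, making the fast gain dynamics (overshoot,
masking) population-wide rather than per-site keeps the decoded
reconstructions free of subpopulation-selective artifacts; per-site
diversity lives entirely in the sustained `d_{i,c}` dynamics, which is
what the adaptation-index analyses measure.

## 4. Analyses

* **High-gamma preprocessing** (for raw multichannel input): 4th-order
  Butterworth 75–150 Hz applied forward–backward (zero phase preserves
  transition-aligned latencies), Hilbert magnitude, polyphase resampling
  to 100 Hz, per-electrode z-scoring against a pre-task silent interval.
  Speech-responsive electrodes: unpaired t of per-interval mean
  responses, speech vs silence, Benjamini–Hochberg at α = 0.01.
* **STRF estimation**: ridge-regularized normal equations on the
  mean-centred lagged design (lags 0–250 ms); the penalty is scale-free
  (units of mean design diagonal power) and can be selected by
  cross-validation over contiguous folds. The excitatory region is the
  4-connected component of kernel values ≥ 0.5 × max containing the
  maximum; best frequency/latency are its power-weighted centroids (log
  axis for frequency). The rate–scale spectrum is the zero-padded 2-D
  FFT magnitude squared folded over both signs; best rate is the
  power-weighted mean of the rate marginal (a "literal" weighting
  variant is provided behind a flag).
* **Reconstruction**: per simulated subject, ridge regression from
  lagged responses (−250–0 ms; i.e. stimulus frame *t* from responses in
  [t, t+250 ms]) to the 13-band spectrogram, trained on the clean-speech
  session only; reconstructions averaged across subjects. The default
  ridge (3.0, scale-free) deliberately trades ~0.1 of training R² for
  out-of-training-statistics generalization: the reconstruction of
  noise-driven activity — never seen in training — is faithful only
  under strong shrinkage.
* **Noise-suppression time course**: transition-aligned R²
  (1 − SS_res/SS_tot, pooled over bands × transitions per frame) of the
  reconstruction against the clean and noisy originals; the switching
  time is the first frame where the clean curve exceeds the noisy curve
  and stays above for ≥ 200 ms.
* **Profile similarity**: DA (0–0.4 s) and AA (2.0–2.4 s) reconstructed
  frequency profiles, peak-normalized and pooled over each condition's
  transitions, compared with the condition's noise profile and the
  clean profile by regression R² (signed squared Pearson). Plain R²
  degenerates when a reference profile is nearly flat (SS_tot → 0 at 13
  bands); the regression form is scale/offset-robust. References are
  content-matched to the same windows. Contiguous transition folds
  (n = 5) give a spread. The DA-vs-clean value is the per-condition
  speech-masking index.
* **Reconstruction adaptation interval**: per aligned frame, paired t
  across transitions of the reconstructed vs clean broadband envelopes
  (baseline-matched over the final quarter of the window to remove
  static bias); the interval ends where the initial contiguous
  significant run ends, with a 250-ms onset grace for neural latency.
* **Adaptation indices**: paired t of DA (0–0.7 s) vs AA (2.0–2.7 s)
  window means across transitions, per electrode × condition; rows
  normalized by min-subtraction then sum-division (all-zero rows flagged
  non-adaptive). The reconstruction profile analyses use their own
  0–0.4/2.0–2.4 s windows; the two sets of constants are never shared.
  Transient duration: per-frame paired t against the AA baseline,
  BH-FDR across frames, duration = end of the initial significant run
  (onset grace 250 ms). Hierarchical clustering of normalized rows:
  Ward's minimum variance for grouping (k = 5 and a 2-cluster "tier"
  cut), UPGMA for display ordering. Tuning-based prediction: OLS of
  normalized AIs on standardized (log best frequency, best rate, speech
  specificity) with a condition-number guard and ridge fallback.
* **Phoneme analysis**: 200-ms onset-aligned spectrogram snippets
  averaged per label, assigned DA/AA by the onset's offset from the
  preceding transition (half-open windows; snippets crossing the next
  transition excluded; natural duration variation not normalized).
  Template–clean Pearson correlations per label with a paired t of
  AA − DA; pairwise dissimilarity by Euclidean distance (default) or
  correlation distance, both exposed — reports name the metric used.
* **Statistics**: paired/unpaired t, BH-FDR and Yates-corrected χ² are
  implemented directly from the standard formulas and verified in-repo
  against scipy/statsmodels to 1e-10; two-sided p-values throughout.
  Degenerate inputs (zero variance) are flagged NaN, never fabricated.
* **Run comparison** (attention-style control): per electrode ×
  condition, unpaired t between two runs' per-transition DA−AA
  differences, plus per-condition paired t of the raw AIs across
  electrodes.

## 5. Study conditions and problem sizes

The default simulated session is 5 minutes (≈ 65 blocks, ≈ 16
transitions per condition) with three simulated subjects of 50
electrodes each — a deliberate ~4× reduction of the reference
experiment's 20 minutes and six subjects/147 electrodes, keeping the
full analysis chain inside desk-scale runtimes. The planted-kernel
recovery study uses 200 s of white-noise stimulus and 50 sites; the
adaptation-index null calibration uses 200 non-adaptive sites on a
stimulus with stationary noise statistics (the calibration property
concerns the statistic, so the stimulus-side transition dynamics are
removed).

## 6. What the simulation does and does not establish

Passing tests show that the pipeline recovers the *generative structure*
of the simulation: planted kernels and tuning parameters, the planted
~0.4-s adaptation time constant (as a ~0.45–0.55 s switching time of the
reconstruction), the restoration of after-adaptation profiles and
phoneme distinctions, the tuning→adaptation linkage, and exact
reproducibility. They do not certify behaviour on clinical recordings:
the simulator is linear (plus pointwise gains) with Gaussian noise; real
high-gamma has non-Gaussian, nonstationary variability, correlated
noise across electrodes, nonlinear encoding, and artifacts that the
preprocessing here does not attempt to remove.

Two desk-scale limits found during development are worth recording.
(1) *During-adaptation profile comparisons are underpowered at this
scale.* With 13 bands, ~16 transitions per condition and 0.4-s windows,
the during-adaptation reconstructed profile is a speech+noise mixture
whose shape correlation with a 13-point reference is dominated by
whichever reference has more structure; a feasibility check showed that
even a perfect reconstruction (the noisy original itself) usually
matches the *clean* profile better than the noise profile at 6 dB SNR.
The after-adaptation comparisons, which hinge on convergence rather than
dominance, are robust. (2) The early post-transition window inherits the
fading previous background from the compressive frontend (§1), which
both blurs the during-adaptation noise reference and contributes a
stimulus-driven DA/AA difference that persists even with all neural
adaptation disabled.

## 7. Reproducibility

Every generator is a pure function of (config, seed); the pipeline
derives per-stage seeds deterministically from the run seed, echoes the
full configuration into the report, and excludes only wall-clock timing
and output paths from the written report, so identical configurations
produce byte-identical report tables.
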