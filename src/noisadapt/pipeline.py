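"""End-to-end orchestration: simulate (or ingest) -> cochlear spectrogram
-> responses -> STRF encoding -> stimulus reconstruction -> adaptation and
phoneme analyses -> machine-readable report.

Every stage draws its randomness from seeds derived deterministically from
the single run seed, so a rerun with an identical config reproduces
byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .adaptation import (
    adaptation_index,
    align_to_transitions,
    cluster_sites,
    normalize_ai,
    predict_ai,
    transient_duration,
)
from .decoder import (
    StimulusDecoder,
    average_reconstructions,
    profile_similarity,
    r2_timecourse,
    reconstruction_adaptation_interval,
)
from .phonemes import dissimilarity_matrix, segment_phonemes, template_correlation
from .preprocess import NeuralRecording, normalize_to_silence, select_speech_responsive
from .spectrogram import Spectrogram, cochlear_spectrogram, reduce_bands
from .stats import paired_t, unpaired_t
from .strf import STRF, speech_specificity
from .synth import (
    CONDITIONS,
    PopulationConfig,
    StimulusConfig,
    TransitionSchedule,
    concat_populations,
    generate_stimulus,
    simulate_population,
    simulate_responses,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_runs"]


@dataclass
class RunConfig:
    """All stage parameters of one end-to-end run."""

    seed: int = 0
    outdir: str | None = None
    # stimulus
    duration_s: float = 240.0
    snr_db: float = 6.0
    block_durations_s: tuple = (3.0, 6.0)
    # spectrogram
    n_filters: int = 128
    n_bands: int = 13
    frame_rate: float = 100.0
    # population: n_subjects independent draws of n_sites each
    n_sites: int = 50
    n_subjects: int = 3
    adaptation_on: bool = True
    # fix the population draw independently of the run seed (e.g. to
    # record two sessions from the same simulated subjects), and the
    # response-noise draw (two sessions of the same stimulus)
    population_seed: int | None = None
    response_seed: int | None = None
    population: dict = field(default_factory=dict)  # PopulationConfig overrides
    # preprocessing / selection
    silence_s: float = 20.0
    selection_alpha: float = 0.01
    # speech/nonspeech battery
    battery_s: float = 80.0
    # encoding / decoding
    max_lag_ms: float = 250.0
    strf_reg: object = 0.1
    decoder_ridge: object = 0.1
    # analysis windows
    ai_da: tuple = (0.0, 0.7)
    ai_aa: tuple = (2.0, 2.7)
    profile_da: tuple = (0.0, 0.4)
    profile_aa: tuple = (2.0, 2.4)
    profile_folds: int = 5
    transient_min_transitions: int = 10
    cluster_k: int = 5
    phoneme_window_ms: float = 200.0
    phoneme_metric: str = "euclidean"
    # stage toggles
    do_select: bool = True
    do_battery: bool = True
    do_decode: bool = True
    do_strf: bool = True
    do_adapt: bool = True
    do_phonemes: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    report: dict
    stimulus: object = None
    population: object = None
    spec_clean: Spectrogram = None
    spec_mixed: Spectrogram = None
    rec_noisy: NeuralRecording = None
    rec_clean: NeuralRecording = None
    recon: Spectrogram = None
    strf_results: object = None
    features: object = None
    ai_table: object = None
    clusters: object = None
    phoneme_r: tuple = None
    phoneme_templates: tuple = None


def _derived_seed(seed: int, k: int) -> int:
    return int((int(seed) % (2**31) + k * 1000003) % (2**31))


def _spec13(wave, fs, cfg: RunConfig) -> Spectrogram:
    full = cochlear_spectrogram(wave, fs, n_filters=cfg.n_filters, frame_rate=cfg.frame_rate)
    return reduce_bands(full, cfg.n_bands)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in dependency order; returns the report
    plus in-memory artefacts. With ``config.outdir`` the report (JSON) and
    the tuning/AI tables (TSV) are written there."""
    t_start = time.time()
    report = {
        "schema_version": 1,
        "package_version": __version__,
        "config": _jsonable(asdict(config)),
        "stages": {},
    }
    s = lambda k: _derived_seed(config.seed, k)
    # response-simulation seeds (separable so two sessions can share a
    # stimulus but draw independent response noise)
    rs = (s if config.response_seed is None
          else (lambda k: _derived_seed(config.response_seed, k)))

    # --- stimulus & spectrograms -----------------------------------------
    stim_cfg = StimulusConfig(
        duration_s=config.duration_s,
        snr_db=config.snr_db,
        block_durations_s=config.block_durations_s,
    )
    stim = generate_stimulus(stim_cfg, s(0))
    schedule = stim.schedule
    spec_mixed = _spec13(stim.mixed_wave, stim.fs, config)
    spec_clean = _spec13(stim.clean_wave, stim.fs, config)
    # per-condition noise components (for stream-resolved adaptation)
    noise_specs = {}
    fs = stim.fs
    for cond in CONDITIONS:
        if cond == "clean":
            continue
        w = np.zeros_like(stim.noise_only_wave)
        for t0, t1, c in schedule.block_bounds():
            if c == cond:
                i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), w.size)
                w[i0:i1] = stim.noise_only_wave[i0:i1]
        spec_c = _spec13(stim.clean_wave + w, fs, config)
        noise_specs[cond] = Spectrogram(
            np.clip(spec_c.values - spec_clean.values, 0.0, None),
            config.frame_rate, spec_clean.center_freqs)
    report["stages"]["stimulus"] = {
        "n_blocks": schedule.n_blocks,
        "n_transitions": len(schedule.transitions()),
        "total_duration_s": schedule.total_duration_s,
        "n_phonemes": len(stim.phonemes),
    }

    # --- per-subject populations & responses ------------------------------
    # each "subject" is an independent population draw; electrode-level
    # analyses pool subjects, the decoder is fitted per subject and the
    # reconstructions are averaged
    pop_cfg = PopulationConfig(
        n_sites=config.n_sites,
        n_bands=config.n_bands,
        frame_rate=config.frame_rate,
        **config.population,
    )
    clean_sched = TransitionSchedule(np.array([0.0]), ["clean"], schedule.total_duration_s)
    pops, recs_noisy, recs_clean = [], [], []
    for g in range(config.n_subjects):
        pop_seed = (s(1 + 10 * g) if config.population_seed is None
                    else _derived_seed(config.population_seed, 1 + 10 * g))
        pop_g = simulate_population(pop_cfg, pop_seed)
        pops.append(pop_g)
        recs_noisy.append(simulate_responses(spec_mixed, spec_clean, pop_g, schedule,
                                             rs(2 + 10 * g),
                                             adaptation_on=config.adaptation_on,
                                             noise_specs=noise_specs))
        recs_clean.append(simulate_responses(spec_clean, spec_clean, pop_g, clean_sched,
                                             rs(3 + 10 * g),
                                             adaptation_on=config.adaptation_on))
    pop = concat_populations(pops) if len(pops) > 1 else pops[0]

    def _pool(recs):
        ids = [f"s{g}_{eid}" for g, r in enumerate(recs) for eid in r.electrode_ids]
        return NeuralRecording(np.concatenate([r.response for r in recs], axis=0),
                               recs[0].fs, ids)

    rec_noisy = _pool(recs_noisy)
    rec_clean = _pool(recs_clean)

    # --- silence normalization + speech-responsive selection --------------
    if config.do_select:
        _run_selection(config, pop, rec_noisy, schedule, report, s)

    # --- speech/nonspeech battery -> speech specificity -------------------
    speech_t = None
    if config.do_battery:
        speech_t = _run_battery(config, pop, report, s)

    result = PipelineResult(report=report, stimulus=stim, population=pop,
                            spec_clean=spec_clean, spec_mixed=spec_mixed,
                            rec_noisy=rec_noisy, rec_clean=rec_clean)

    # --- encoding ----------------------------------------------------------
    features = None
    if config.do_strf:
        strf_res = STRF(spec_clean, rec_clean, max_lag_ms=config.max_lag_ms).fit(
            reg=config.strf_reg)
        tuning = strf_res.tuning_table()
        import pandas as pd

        if speech_t is not None:
            features = pd.DataFrame({
                "best_frequency": np.log2(tuning["best_freq_hz"].to_numpy()),
                "best_rate": tuning["best_rate_hz"].to_numpy(),
                "speech_t": speech_t,
            })
        result.strf_results = strf_res
        result.features = features
        report["stages"]["strf"] = {
            "median_best_freq_hz": float(np.nanmedian(tuning["best_freq_hz"])),
            "median_latency_ms": float(np.nanmedian(tuning["latency_ms"])),
            "median_best_rate_hz": float(np.nanmedian(tuning["best_rate_hz"])),
        }

    # --- decoding ----------------------------------------------------------
    if config.do_decode:
        recons = []
        ridges = []
        for g in range(config.n_subjects):
            dec = StimulusDecoder(recs_clean[g], spec_clean,
                                  max_lag_ms=config.max_lag_ms).fit(
                ridge=config.decoder_ridge)
            dec.training_group_id = f"s{g}"
            recons.append(dec.reconstruct(recs_noisy[g]))
            ridges.append(dec.ridge)
        recon = average_reconstructions(recons)
        result.recon = recon
        r2c, r2n, switch_ms = r2_timecourse(recon, spec_clean, spec_mixed, schedule)
        prof = profile_similarity(recon, spec_clean, spec_mixed, schedule,
                                  da=config.profile_da, aa=config.profile_aa,
                                  n_folds=config.profile_folds)
        adapt_int_ms = reconstruction_adaptation_interval(recon, spec_clean, schedule)
        report["stages"]["decode"] = {
            "ridge": ridges,
            "switch_time_ms": switch_ms,
            "adaptation_interval_ms": adapt_int_ms,
            "profile_similarity": {
                c: {k: v for k, v in d.items() if k != "folds"}
                for c, d in prof.items()
            },
            "mean_r2_da_vs_noise": float(np.mean(
                [d["r2_da_vs_noise"] for d in prof.values()])),
            "mean_r2_aa_vs_clean": float(np.mean(
                [d["r2_aa_vs_clean"] for d in prof.values()])),
        }

    # --- adaptation --------------------------------------------------------
    if config.do_adapt:
        aligned = align_to_transitions(rec_noisy, schedule)
        trans_dur = transient_duration(
            aligned, baseline=config.ai_aa,
            min_transitions=config.transient_min_transitions)
        table = normalize_ai(adaptation_index(rec_noisy, schedule,
                                              da=config.ai_da, aa=config.ai_aa))
        k = min(config.cluster_k, int((~table.non_adaptive).sum()))
        clusters = cluster_sites(table, linkage="ward", k=k)
        result.ai_table = table
        result.clusters = clusters
        dur_mat = np.stack([trans_dur[c] for c in sorted(trans_dur)])
        sig_any = dur_mat.max(axis=0) > 0
        report["stages"]["adapt"] = {
            # mean over electrode-conditions with a significant transient
            "mean_transient_duration_ms": float(dur_mat[dur_mat > 0].mean())
            if (dur_mat > 0).any() else 0.0,
            "transient_duration_ms": {
                c: float(d[d > 0].mean()) if (d > 0).any() else 0.0
                for c, d in trans_dur.items()},
            "n_no_transient": int((~sig_any).sum()),
            "n_non_adaptive": int(table.non_adaptive.sum()),
            "cluster_sizes": np.bincount(clusters.labels, minlength=k + 1)[1:].tolist(),
        }
        if features is not None:
            pred = predict_ai(table, features)
            report["stages"]["adapt"]["predict_ai"] = {
                c: {"r2": d["r2"], "coef": _jsonable(d["coef"])}
                for c, d in pred.items()
            }

    # --- phonemes ----------------------------------------------------------
    if config.do_phonemes and config.do_decode:
        clean_tpl = segment_phonemes(spec_clean, stim.phonemes,
                                     window_ms=config.phoneme_window_ms)
        recon_tpl = segment_phonemes(result.recon, stim.phonemes, schedule,
                                     da=config.profile_da, aa=config.profile_aa,
                                     window_ms=config.phoneme_window_ms)
        labels, r_da, r_aa, (t_corr, p_corr) = template_correlation(recon_tpl, clean_tpl)
        dists = {}
        for metric in ("euclidean", "correlation"):
            _, dists[f"mean_distance_da_{metric}"] = dissimilarity_matrix(
                recon_tpl[0], metric=metric)
            _, dists[f"mean_distance_aa_{metric}"] = dissimilarity_matrix(
                recon_tpl[1], metric=metric)
        report["stages"]["phonemes"] = {
            "n_labels": len(labels),
            "mean_r_da": float(r_da.mean()),
            "mean_r_aa": float(r_aa.mean()),
            "corr_paired_t": t_corr,
            "corr_paired_p": p_corr,
            "metric_default": config.phoneme_metric,
            **dists,
        }
        result.phoneme_r = (labels, r_da, r_aa)
        result.phoneme_templates = (recon_tpl, clean_tpl)

    report["elapsed_s"] = round(time.time() - t_start, 3)
    if config.outdir:
        _write_outputs(config, result)
    return result


def _run_selection(config, pop, rec_noisy, schedule, report, s):
    """Silence-normalize against a simulated pre-task silent interval and
    select speech-responsive electrodes (speech vs silence, FDR)."""
    zero = Spectrogram(
        np.zeros((int(round(config.silence_s * config.frame_rate)), config.n_bands)),
        config.frame_rate)
    sil_sched = TransitionSchedule(np.array([0.0]), ["clean"], config.silence_s)
    rec_sil = simulate_responses(zero, zero, pop, sil_sched, s(4))
    combined = NeuralRecording(
        np.concatenate([rec_sil.response, rec_noisy.response], axis=1),
        rec_noisy.fs, list(rec_noisy.electrode_ids))
    combined = normalize_to_silence(combined, (0.0, config.silence_s))
    speech_ivals = [
        (t0 + config.silence_s, t1 + config.silence_s)
        for t0, t1, c in schedule.block_bounds() if c == "clean"
    ][:12]
    n_chunks = max(2, min(12, int(config.silence_s // 2)))
    edges = np.linspace(0, config.silence_s, n_chunks + 1)
    sil_ivals = list(zip(edges[:-1], edges[1:]))
    sel_mask, _ = select_speech_responsive(
        combined, speech_ivals, sil_ivals, alpha=config.selection_alpha)
    report["stages"]["selection"] = {
        "n_speech_responsive": int(sel_mask.sum()),
        "n_electrodes": int(sel_mask.size),
    }


def _run_battery(config, pop, report, s):
    """Speech/nonspeech sound battery: speech gated off during noise
    blocks; each block is one sound event."""
    bat_cfg = StimulusConfig(duration_s=config.battery_s, snr_db=config.snr_db,
                             block_durations_s=config.block_durations_s,
                             speech_in_noise=False)
    bat = generate_stimulus(bat_cfg, s(5))
    bat_mixed = _spec13(bat.mixed_wave, bat.fs, config)
    bat_clean = _spec13(bat.clean_wave, bat.fs, config)
    rec_bat = simulate_responses(bat_mixed, bat_clean, pop, bat.schedule, s(6),
                                 adaptation_on=config.adaptation_on)
    events = [((t0, min(t1, rec_bat.duration_s)), c == "clean")
              for t0, t1, c in bat.schedule.block_bounds()]
    speech_t = speech_specificity(rec_bat, events)
    report["stages"]["speech_specificity"] = {
        "mean_t_specific": float(np.mean(speech_t[pop.is_speech_specific]))
        if pop.is_speech_specific.any() else None,
        "mean_t_other": float(np.mean(speech_t[~pop.is_speech_specific])),
    }
    return speech_t


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_outputs(config: RunConfig, result: PipelineResult):
    os.makedirs(config.outdir, exist_ok=True)
    # wall-clock timing and output paths are provenance, not results: they
    # are excluded from the written report so identical runs are
    # byte-identical
    report = json.loads(json.dumps(_jsonable(result.report)))
    report.pop("elapsed_s", None)
    report["config"]["outdir"] = None
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if result.ai_table is not None:
        result.ai_table.to_dataframe().to_csv(
            os.path.join(config.outdir, "adaptation_indices.tsv"), sep="\t")
    if result.strf_results is not None:
        result.strf_results.tuning_table().to_csv(
            os.path.join(config.outdir, "tuning.tsv"), sep="\t", index=False)
    if result.population is not None:
        result.population.write_sidecar(os.path.join(config.outdir, "ground_truth.json"))
    if result.stimulus is not None:
        result.stimulus.write(os.path.join(config.outdir, "stimulus"))


def compare_runs(a, b, alpha: float = 0.05) -> dict:
    """Compare the adaptation indices of two runs with matched electrodes.

    Per electrode and condition, an unpaired t-test between the two runs'
    per-transition DA-AA response differences; plus, per condition, a
    paired t across electrodes of the raw AIs (the attention-style
    population comparison).

    Returns {"frac_nonsignificant", "pair_pvalues", "condition_tests"}.
    """
    ta = a.ai_table if isinstance(a, PipelineResult) else a
    tb = b.ai_table if isinstance(b, PipelineResult) else b
    if ta.raw.shape != tb.raw.shape or list(ta.electrode_ids) != list(tb.electrode_ids):
        raise ValueError("electrode sets do not match")
    n_el = ta.raw.shape[0]
    pair_p = {}
    n_tested = 0
    n_nonsig = 0
    for cond in ta.condition_order:
        if cond not in ta.diffs or cond not in tb.diffs:
            continue
        pv = np.empty(n_el)
        for e in range(n_el):
            _, pv[e] = unpaired_t(ta.diffs[cond][:, e], tb.diffs[cond][:, e])
        pair_p[cond] = pv
        ok = np.isfinite(pv)
        n_tested += int(ok.sum())
        n_nonsig += int((pv[ok] >= alpha).sum())
    cond_tests = {}
    for j, cond in enumerate(ta.condition_order):
        xa, xb = ta.raw[:, j], tb.raw[:, j]
        m = np.isfinite(xa) & np.isfinite(xb)
        cond_tests[cond] = paired_t(xa[m], xb[m]) if m.sum() >= 2 else (np.nan, np.nan)
    return {
        "frac_nonsignificant": n_nonsig / n_tested if n_tested else np.nan,
        "pair_pvalues": pair_p,
        "condition_tests": cond_tests,
    }
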