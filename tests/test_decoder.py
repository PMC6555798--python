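"""Stimulus reconstruction: closed-form equivalence, algebraic identities,
and the transition-aligned noise-suppression analyses on constructed
inputs."""

import numpy as np
import pytest

from noisadapt._design import lagged_design_anticausal
from noisadapt.decoder import (
    StimulusDecoder,
    profile_similarity,
    r2_timecourse,
    r_squared,
    reconstruction_adaptation_interval,
    regression_r2,
)
from noisadapt.preprocess import NeuralRecording
from noisadapt.spectrogram import Spectrogram
from noisadapt.synth import TransitionSchedule

from conftest import periodic_schedule


def make_spec(vals):
    return Spectrogram(vals, 100.0, np.geomspace(180, 5400, vals.shape[1]))


class TestFit:
    def test_tiny_instance_matches_explicit_normal_equations(self, rng):
        """2 electrodes, 1 band, 3 lags, 40 frames vs dense solve."""
        resp = NeuralRecording(rng.standard_normal((2, 40)), 100.0)
        stim = make_spec(rng.random((40, 1)))
        lam = 0.5
        res = StimulusDecoder(resp, stim, max_lag_ms=20.0).fit(ridge=lam)
        X = lagged_design_anticausal(resp.response.T, 3)
        Xc = X - X.mean(axis=0)
        Yc = stim.values - stim.values.mean(axis=0)
        scale = np.trace(Xc.T @ Xc) / 6
        W = np.linalg.solve(Xc.T @ Xc + lam * scale * np.eye(6), Xc.T @ Yc)
        assert np.allclose(res.weights, W, atol=1e-8)

    def test_exact_linear_responses_reconstruct_training(self, rng):
        """Responses that are exact linear functions of the spectrogram:
        training reconstruction R^2 >= 0.99 per band at small ridge."""
        stim = make_spec(rng.random((2000, 3)))
        mix = rng.standard_normal((3, 6))  # bands -> electrodes
        resp = NeuralRecording((stim.values @ mix).T, 100.0)
        res = StimulusDecoder(resp, stim).fit(ridge=1e-8)
        recon = res.reconstruct(resp)
        for b in range(3):
            assert r_squared(recon.values[:, b], stim.values[:, b]) >= 0.99

    def test_zero_responses_give_intercept_reconstruction(self, rng):
        stim = make_spec(rng.random((300, 4)))
        resp = NeuralRecording(np.zeros((2, 300)), 100.0)
        res = StimulusDecoder(resp, stim).fit(ridge=1.0)
        assert np.allclose(res.weights, 0.0)
        assert np.allclose(res.intercept, stim.values.mean(axis=0))
        recon = res.reconstruct(resp)
        assert np.allclose(recon.values, stim.values.mean(axis=0)[None, :])

    def test_reconstruction_linearity(self, rng):
        stim = make_spec(rng.random((500, 2)))
        r1 = NeuralRecording(rng.standard_normal((3, 500)), 100.0)
        r2 = NeuralRecording(rng.standard_normal((3, 500)), 100.0)
        filt = StimulusDecoder(r1, stim).fit(ridge=0.1)
        a, b = 0.3, 1.2
        combo = NeuralRecording(a * r1.response + b * r2.response, 100.0)
        lhs = filt.reconstruct(combo).values
        rhs = (a * filt.reconstruct(r1).values + b * filt.reconstruct(r2).values
               + (1 - a - b) * filt.intercept[None, :])
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_electrode_mismatch_raises(self, rng):
        stim = make_spec(rng.random((100, 2)))
        resp = NeuralRecording(rng.standard_normal((2, 100)), 100.0)
        res = StimulusDecoder(resp, stim).fit(ridge=0.1)
        other = NeuralRecording(rng.standard_normal((3, 100)), 100.0)
        with pytest.raises(ValueError):
            res.reconstruct(other)

    def test_misalignment_raises(self, rng):
        stim = make_spec(rng.random((100, 2)))
        with pytest.raises(ValueError):
            StimulusDecoder(NeuralRecording(rng.standard_normal((2, 99)), 100.0), stim)


class TestRSquared:
    def test_equals_one_minus_ss_ratio_and_bounded(self, rng):
        ref = rng.standard_normal(100)
        pred = ref + 0.1 * rng.standard_normal(100)
        r2 = r_squared(pred, ref)
        assert r2 <= 1.0
        manual = 1 - np.sum((pred - ref) ** 2) / np.sum((ref - ref.mean()) ** 2)
        assert r2 == pytest.approx(manual)

    def test_equals_squared_pearson_in_fitted_univariate_case(self, rng):
        x = rng.standard_normal(200)
        ref = 2.0 * x + 1.0 + 0.3 * rng.standard_normal(200)
        # fitted prediction (OLS of ref on x)
        A = np.vstack([x, np.ones_like(x)]).T
        pred = A @ np.linalg.lstsq(A, ref, rcond=None)[0]
        r = np.corrcoef(pred, ref)[0, 1]
        assert r_squared(pred, ref) == pytest.approx(r**2, abs=1e-10)
        assert regression_r2(pred, ref) == pytest.approx(r**2, abs=1e-10)


def constructed_recon(seed=0, n_blocks=40, recon_source="clean"):
    """Spectrogram triple (recon, clean, noisy) with known structure."""
    rng = np.random.default_rng(seed)
    sched = periodic_schedule(n_blocks=n_blocks, block_s=3.0)
    T = int(sched.total_duration_s * 100)
    clean = rng.random((T, 13)) * 0.1
    noisy = clean.copy()
    for t0, t1, cond in sched.block_bounds():
        if cond == "clean":
            continue
        prof = {"jet": 10, "city": 6, "bar": 2}[cond]
        band = np.exp(-((np.arange(13) - prof) ** 2) / 3.0)
        noisy[int(t0 * 100) : int(t1 * 100)] += 0.08 * band[None, :]
    src = {"clean": clean, "noisy": noisy}[recon_source]
    return (make_spec(src), make_spec(clean), make_spec(noisy), sched)


class TestR2Timecourse:
    def test_recon_equals_clean(self):
        recon, clean, noisy, sched = constructed_recon()
        r2c, r2n, sw = r2_timecourse(recon, clean, noisy, sched)
        assert np.allclose(r2c, 1.0)
        assert sw == 0.0

    def test_recon_equals_noisy_reports_absent_switch(self):
        recon, clean, noisy, sched = constructed_recon(recon_source="noisy")
        r2c, r2n, sw = r2_timecourse(recon, clean, noisy, sched)
        assert np.allclose(r2n, 1.0)
        assert sw is None

    def test_too_few_transitions_raise(self):
        recon, clean, noisy, sched = constructed_recon(n_blocks=5)
        with pytest.raises(ValueError):
            r2_timecourse(recon, clean, noisy, sched)


class TestProfileSimilarity:
    def test_recon_equals_clean_gives_aa_match_one(self):
        recon, clean, noisy, sched = constructed_recon()
        out = profile_similarity(recon, clean, noisy, sched)
        for cond, d in out.items():
            assert d["r2_aa_vs_clean"] == pytest.approx(1.0, abs=1e-9)

    def test_label_shuffle_destroys_da_noise_match(self):
        """Grouping reconstructed DA profiles by permuted condition labels
        must break their match with the true conditions' noise profiles."""
        import itertools

        recon, clean, noisy, sched = constructed_recon(recon_source="noisy")
        fr = 100
        nv = np.clip(noisy.values - clean.values, 0.0, None)
        conds = ("jet", "city", "bar")

        def grouped_profiles(label_map):
            prof = {}
            for cond in conds:
                idx = [int(t * fr) for t, c in sched.transitions()
                       if label_map.get(c, c) == cond
                       and t * fr + 240 <= recon.n_frames]
                prof[cond] = np.mean(
                    [recon.values[i : i + 40].mean(axis=0) for i in idx], axis=0)
            return prof

        refs = {}
        for cond in conds:
            idx = [int(t * fr) for t, c in sched.transitions()
                   if c == cond and t * fr + 240 <= recon.n_frames]
            refs[cond] = np.mean([nv[i + 200 : i + 240].mean(axis=0) for i in idx],
                                 axis=0)

        def score(label_map):
            prof = grouped_profiles(label_map)
            return np.mean([regression_r2(prof[c], refs[c]) for c in conds])

        matched = score({})
        perms = [dict(zip(conds, p)) for p in itertools.permutations(conds)
                 if p != conds]
        worse = sum(score(m) < matched for m in perms)
        assert worse >= 0.95 * len(perms)

    def test_too_few_transitions_per_condition_raise(self):
        recon, clean, noisy, sched = constructed_recon(n_blocks=8)
        with pytest.raises(ValueError):
            profile_similarity(recon, clean, noisy, sched)


class TestReconstructionAdaptationInterval:
    def test_recon_equals_clean_gives_zero(self):
        recon, clean, noisy, sched = constructed_recon()
        assert reconstruction_adaptation_interval(recon, clean, sched) == 0.0

    def test_planted_400ms_divergence_recovered(self):
        _, clean, noisy, sched = constructed_recon()
        vals = clean.values.copy()
        # plant an exponential divergence of ~400 ms extent after every
        # transition (hits zero amplitude beyond 0.4 s)
        for t_k, cond in sched.transitions():
            i0 = int(t_k * 100)
            u = np.arange(40)
            vals[i0 : i0 + 40] += (0.3 * np.exp(-u / 12.0))[:, None] * (u < 40)[:, None]
        recon = make_spec(vals)
        dur = reconstruction_adaptation_interval(recon, clean, sched, alpha=0.01)
        assert 300.0 <= dur <= 500.0

    def test_alpha_one_flags_full_window(self):
        recon, clean, noisy, sched = constructed_recon(recon_source="noisy")
        dur = reconstruction_adaptation_interval(recon, clean, sched, alpha=1.0,
                                                 window_s=2.0)
        assert dur == pytest.approx(2000.0)
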