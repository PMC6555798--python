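"""Transition-aligned analysis: alignment, transients, adaptation indices,
normalization, clustering, and tuning-based prediction."""

import numpy as np
import pytest
from scipy import stats as sps

from noisadapt.adaptation import (
    AdaptationTable,
    adaptation_index,
    align_to_transitions,
    cluster_sites,
    normalize_ai,
    predict_ai,
    transient_duration,
)
from noisadapt.preprocess import NeuralRecording

from conftest import periodic_schedule


def flat_recording(n_el=3, dur_s=60.0, fs=100.0, value=1.0):
    return NeuralRecording(np.full((n_el, int(dur_s * fs)), value), fs)


class TestAlign:
    def test_constant_response_constant_mean_zero_variance(self, schedule20):
        rec = flat_recording()
        al = align_to_transitions(rec, schedule20, window_s=(-1.0, 2.0))
        for cond, tens in al.tensors.items():
            assert np.allclose(tens, 1.0)
            assert np.allclose(tens.std(axis=0), 0.0)

    def test_planted_transient_appears_only_in_its_condition(self, schedule20):
        fs = 100.0
        rec = flat_recording(n_el=1)
        for t_k, cond in schedule20.transitions():
            if cond == "jet":
                i = int((t_k + 0.1) * fs)
                rec.response[0, i : i + 5] += 3.0
        al = align_to_transitions(rec, schedule20, window_s=(-0.5, 1.0))
        means = al.mean_traces()
        jet = means["jet"][0]
        peak_frame = int(np.argmax(jet))
        assert 58 <= peak_frame <= 66  # +100 ms after onset (frame 50+10)
        for cond in ("city", "bar", "clean"):
            assert np.allclose(means[cond][0], 1.0)

    def test_window_exceeding_block_flags_overlap(self, schedule20):
        rec = flat_recording()
        al = align_to_transitions(rec, schedule20, window_s=(-1.0, 5.0))
        # blocks are 3 s, so the last 2 s of every window extend into the
        # next block and must be flagged
        for cond, ov in al.overlap.items():
            assert ov[:, -10:].all()

    def test_edge_transitions_dropped_and_counted(self, schedule20):
        rec = NeuralRecording(np.ones((2, int(100 * 55))), 100.0)  # short
        al = align_to_transitions(rec, schedule20, window_s=(-1.0, 3.0))
        assert al.n_dropped >= 1


class TestTransientDuration:
    def test_null_has_zero_duration_in_most_seeds(self):
        hits = 0
        sched = periodic_schedule(n_blocks=44)
        for seed in range(12):
            rng = np.random.default_rng(seed)
            rec = NeuralRecording(
                rng.standard_normal((1, int(100 * sched.total_duration_s))), 100.0)
            al = align_to_transitions(rec, sched, window_s=(-0.5, 2.7))
            durs = transient_duration(al, baseline=(2.0, 2.7), alpha=0.01)
            hits += any(d[0] > 0 for d in durs.values())
        assert hits <= 2  # ~null: no transient in >= 10/12 seeds

    def test_planted_600ms_overshoot_recovered(self):
        sched = periodic_schedule(n_blocks=44)
        fs = 100.0
        rng = np.random.default_rng(0)
        resp = 0.2 * rng.standard_normal((1, int(fs * sched.total_duration_s)))
        for t_k, cond in sched.transitions():
            i = int(t_k * fs)
            resp[0, i : i + 60] += 2.0  # 600-ms plateau
        rec = NeuralRecording(resp, fs)
        al = align_to_transitions(rec, sched, window_s=(-0.5, 2.7))
        durs = transient_duration(al, baseline=(2.0, 2.7), alpha=0.01)
        for cond, d in durs.items():
            assert 450.0 <= d[0] <= 750.0

    def test_duration_never_exceeds_window(self):
        sched = periodic_schedule(n_blocks=44)
        rec = NeuralRecording(
            np.random.default_rng(1).standard_normal(
                (2, int(100 * sched.total_duration_s))) + 5.0, 100.0)
        al = align_to_transitions(rec, sched, window_s=(-0.5, 2.7))
        durs = transient_duration(al, baseline=(2.0, 2.7))
        for d in durs.values():
            assert np.all(d <= 2700.0)

    def test_baseline_overlapping_da_window_raises(self, schedule20):
        rec = flat_recording()
        al = align_to_transitions(rec, schedule20, window_s=(-0.5, 2.7))
        with pytest.raises(ValueError):
            transient_duration(al, baseline=(0.5, 1.0))


class TestAdaptationIndex:
    def test_equal_da_aa_gives_zero_t(self):
        sched = periodic_schedule(n_blocks=24)
        rng = np.random.default_rng(0)
        # responses periodic with the block so DA and AA means repeat, but
        # add per-transition jitter so variance is nonzero
        fs = 100.0
        T = int(fs * sched.total_duration_s)
        resp = np.tile(np.ones(300), T // 300 + 1)[:T][None, :]
        resp = resp + 0.01 * rng.standard_normal((1, T))
        table = adaptation_index(NeuralRecording(resp, fs), sched)
        assert np.all(np.abs(table.raw[np.isfinite(table.raw)]) < 2.5)

    def test_hand_computed_paired_t(self):
        """Construct per-transition DA-AA differences {2,1,3,2} for one
        condition and compare with the closed-form paired t."""
        sched = periodic_schedule(n_blocks=9, block_s=3.0,
                                  conds=("jet", "clean"))
        fs = 100.0
        T = int(fs * sched.total_duration_s)
        resp = np.zeros((1, T))
        diffs = [2.0, 1.0, 3.0, 2.0]
        k = 0
        for t_k, cond in sched.transitions():
            if cond != "jet":
                continue
            i = int(t_k * fs)
            resp[0, i : i + 70] = diffs[k] + k * 0.5  # DA window value
            resp[0, i + 200 : i + 270] = k * 0.5  # AA window value
            k += 1
        table = adaptation_index(NeuralRecording(resp, fs), sched)
        d = np.array(diffs)
        expected = d.mean() / (d.std(ddof=1) / 2.0)
        j = list(table.condition_order).index("jet")
        assert table.raw[0, j] == pytest.approx(expected, abs=1e-6)

    def test_degenerate_constant_differences_flagged(self):
        sched = periodic_schedule(n_blocks=9, conds=("jet", "clean"))
        fs = 100.0
        T = int(fs * sched.total_duration_s)
        resp = np.zeros((1, T))
        for t_k, cond in sched.transitions():
            if cond == "jet":
                i = int(t_k * fs)
                resp[0, i : i + 70] = 1.0  # identical difference every time
        table = adaptation_index(NeuralRecording(resp, fs), sched)
        j = list(table.condition_order).index("jet")
        assert np.isnan(table.raw[0, j])

    def test_antisymmetry_swapping_windows(self):
        sched = periodic_schedule(n_blocks=24)
        rng = np.random.default_rng(2)
        rec = NeuralRecording(
            rng.standard_normal((3, int(100 * sched.total_duration_s))), 100.0)
        t1 = adaptation_index(rec, sched, da=(0.0, 0.7), aa=(2.0, 2.7))
        t2 = adaptation_index(rec, sched, da=(2.0, 2.7), aa=(0.0, 0.7))
        m = np.isfinite(t1.raw)
        assert np.allclose(t1.raw[m], -t2.raw[m], atol=1e-10)


class TestNormalizeAI:
    def test_forced_arithmetic_example(self):
        table = AdaptationTable(raw=np.array([[2.0, 1.0, 3.0, 1.0]]))
        out = normalize_ai(table)
        assert np.allclose(out.norm[0], [1 / 3, 0.0, 2 / 3, 0.0])

    def test_equal_rows_flagged_non_adaptive(self):
        table = normalize_ai(AdaptationTable(raw=np.array([[1.0, 1.0, 1.0, 1.0]])))
        assert table.non_adaptive[0]

    def test_invariant_min_zero_sum_one(self, rng):
        raw = rng.standard_normal((30, 4)) * 3
        table = normalize_ai(AdaptationTable(raw=raw))
        ok = ~table.non_adaptive
        assert np.allclose(table.norm[ok].min(axis=1), 0.0, atol=1e-9)
        assert np.allclose(table.norm[ok].sum(axis=1), 1.0, atol=1e-9)


class TestClusterSites:
    def test_two_planted_archetypes_recovered_exactly(self, rng):
        clean_like = np.array([0.7, 0.1, 0.1, 0.1])
        noise_like = np.array([0.0, 0.4, 0.3, 0.3])
        rows = []
        truth = []
        for i in range(40):
            arch = clean_like if i % 2 == 0 else noise_like
            rows.append(arch + rng.normal(0, 0.02, 4))
            truth.append(i % 2)
        raw = np.array(rows)
        table = normalize_ai(AdaptationTable(raw=raw))
        res = cluster_sites(table, linkage="ward", k=2)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_duplicate_rows_cluster_together(self):
        raw = np.array([[2.0, 1.0, 0.5, 0.1]] * 3 + [[0.1, 0.5, 1.0, 2.0]] * 3)
        table = normalize_ai(AdaptationTable(raw=raw))
        res = cluster_sites(table, k=2)
        assert len(set(res.labels[:3])) == 1
        assert len(set(res.labels[3:])) == 1
        assert res.labels[0] != res.labels[3]

    def test_ward_merge_sequence_matches_brute_force(self):
        """6-point configuration: scipy's minimum-variance merges equal a
        brute-force greedy Ward merge enumeration."""
        pts = np.array([
            [0.0, 0.0, 0.5, 0.5],
            [0.05, 0.0, 0.5, 0.45],
            [1.0, 0.0, 0.0, 0.0],
            [1.05, 0.05, 0.0, -0.1],
            [0.5, 1.0, -0.5, 0.2],
            [0.55, 1.0, -0.45, 0.2],
        ])
        # brute-force greedy Ward: repeatedly merge the pair of clusters
        # minimizing the increase in total within-cluster variance
        clusters = [[i] for i in range(6)]
        merges = []
        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    ca, cb = clusters[a], clusters[b]
                    na, nb = len(ca), len(cb)
                    d2 = np.sum((pts[ca].mean(0) - pts[cb].mean(0)) ** 2)
                    cost = na * nb / (na + nb) * d2
                    if best is None or cost < best[0]:
                        best = (cost, a, b)
            _, a, b = best
            merges.append(sorted(clusters[a] + clusters[b]))
            merged = clusters[a] + clusters[b]
            clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
            clusters.append(merged)
        from scipy.cluster import hierarchy as hier

        Z = hier.linkage(pts, method="ward")
        # reconstruct scipy's merge membership sequence
        members = {i: [i] for i in range(6)}
        scipy_merges = []
        for step, (i, j, _, _) in enumerate(Z):
            m = sorted(members[int(i)] + members[int(j)])
            members[6 + step] = m
            scipy_merges.append(m)
        assert merges == scipy_merges

    def test_k_greater_than_n_raises(self, rng):
        table = normalize_ai(AdaptationTable(raw=rng.standard_normal((4, 4))))
        with pytest.raises(ValueError):
            cluster_sites(table, k=10)


class TestPredictAI:
    def make_features(self, rng, n):
        import pandas as pd

        return pd.DataFrame({
            "best_frequency": rng.standard_normal(n),
            "best_rate": rng.standard_normal(n),
            "speech_t": rng.standard_normal(n),
        })

    def test_exactly_linear_ai_gives_r2_one(self, rng):
        n = 40
        feats = self.make_features(rng, n)
        z = (feats - feats.mean()) / feats.std(ddof=0)
        y = 0.1 + 0.05 * z["best_frequency"] + 0.03 * z["speech_t"]
        raw = np.column_stack([y, y * 0.5, y * 0.2, np.zeros(n) - 1])
        table = normalize_ai(AdaptationTable(raw=raw))
        # overwrite norm with the linear construction directly
        table.norm = np.column_stack([y, y, y, y]).astype(float)
        table.non_adaptive = np.zeros(n, dtype=bool)
        out = predict_ai(table, feats)
        for cond in table.condition_order:
            assert out[cond]["r2"] == pytest.approx(1.0, abs=1e-9)
            assert out[cond]["coef"]["best_frequency"] == pytest.approx(0.05, abs=1e-9)

    def test_permuted_rows_give_near_zero_r2(self, rng):
        n = 60
        feats = self.make_features(rng, n)
        y = feats["best_frequency"].to_numpy() * 0.2 + 0.5
        bad = 0
        for _ in range(30):
            perm = rng.permutation(n)
            table = AdaptationTable(raw=np.tile(y[perm, None], (1, 4)))
            table.norm = np.tile(y[perm, None], (1, 4))
            table.non_adaptive = np.zeros(n, dtype=bool)
            out = predict_ai(table, feats)
            bad += out["jet"]["r2"] > 0.1
        assert bad <= 2  # >= ~95% of permutations destroy the fit

    def test_too_few_electrodes_raise(self, rng):
        table = AdaptationTable(raw=np.ones((5, 4)))
        table.norm = np.ones((5, 4)) / 4
        table.non_adaptive = np.zeros(5, dtype=bool)
        with pytest.raises(ValueError):
            predict_ai(table, self.make_features(rng, 5))
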