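"""Transition-aligned response analysis: transients, adaptation indices,
clustering of adaptation patterns, and tuning-based prediction.

The adaptation index (AI) of a site for a background condition is the
t-value of a paired t-test between its mean response 0-0.7 s after
transitions into that condition (during adaptation, DA) and 2-2.7 s after
(after adaptation, AA). Per site, AIs are normalized by subtracting the
minimum over the four conditions and dividing by the sum of the shifted
values, so each valid row has min 0 and sum 1; rows whose shifted values
are all zero are flagged non-adaptive.

Sites are grouped by hierarchical clustering of the normalized AI rows
(Euclidean distance; Ward's minimum-variance linkage for grouping, UPGMA
for display ordering), and the AIs are predicted from standardized tuning
parameters (best frequency, best rate, speech specificity) by ordinary
least squares, whose standardized coefficients are the per-parameter main
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as _hier

from .preprocess import NeuralRecording
from .stats import paired_t, fdr_bh
from .synth import CONDITIONS, TransitionSchedule

__all__ = [
    "AlignedResponses",
    "AdaptationTable",
    "align_to_transitions",
    "transient_duration",
    "adaptation_index",
    "normalize_ai",
    "cluster_sites",
    "predict_ai",
    "DA_WINDOW_AI",
    "AA_WINDOW_AI",
]

# AI windows; the reconstruction profile analyses use their own (0-0.4 /
# 2.0-2.4 s) constants in decoder.profile_similarity — never shared silently
DA_WINDOW_AI = (0.0, 0.7)
AA_WINDOW_AI = (2.0, 2.7)


@dataclass
class AlignedResponses:
    """Per-condition transition-aligned tensors.

    ``tensors[cond]`` has shape (transitions x electrodes x frames) with
    frame 0 at the transition onset; ``overlap[cond]`` flags, per
    transition and frame, context that extends into a neighbouring block
    (windows longer than the block are still returned but flagged).
    """

    tensors: dict
    overlap: dict
    window_s: tuple
    frame_rate: float
    n_dropped: int
    electrode_ids: list

    def mean_traces(self) -> dict:
        """Condition -> (electrodes x frames) mean over transitions."""
        return {c: t.mean(axis=0) for c, t in self.tensors.items()}


def align_to_transitions(
    rec: NeuralRecording,
    schedule: TransitionSchedule,
    window_s: tuple[float, float] = (-1.0, 3.0),
) -> AlignedResponses:
    """Cut the recording around every transition, grouped by the new
    condition. Transitions whose window is not fully inside the recording
    are dropped (count reported); a condition with no usable transition is
    an error."""
    fr = rec.fs
    i_lo = int(round(window_s[0] * fr))
    i_hi = int(round(window_s[1] * fr))
    tensors = {}
    overlap = {}
    dropped = 0
    t_axis = np.arange(i_lo, i_hi) / fr
    trans = schedule.transitions()
    for k, (t_k, cond) in enumerate(trans):
        c0 = int(round(t_k * fr))
        if c0 + i_lo < 0 or c0 + i_hi > rec.n_samples:
            dropped += 1
            continue
        seg = rec.response[:, c0 + i_lo : c0 + i_hi]
        # context outside the current block (before the transition is by
        # definition the previous block; flag only beyond-the-next-onset)
        nxt = trans[k + 1][0] if k + 1 < len(trans) else schedule.total_duration_s
        ov = (t_axis >= (nxt - t_k)) | (t_axis < -(t_k - _prev_onset(schedule, t_k)))
        tensors.setdefault(cond, []).append(seg)
        overlap.setdefault(cond, []).append(ov)
    present = {c for c in (c for _, c in trans)}
    for cond in present:
        if cond not in tensors:
            raise ValueError(f"no usable transitions for condition {cond!r}")
    return AlignedResponses(
        tensors={c: np.stack(v) for c, v in tensors.items()},
        overlap={c: np.stack(v) for c, v in overlap.items()},
        window_s=window_s,
        frame_rate=fr,
        n_dropped=dropped,
        electrode_ids=list(rec.electrode_ids),
    )


def _prev_onset(schedule: TransitionSchedule, t_k: float) -> float:
    onsets = schedule.onsets
    i = int(np.searchsorted(onsets, t_k)) - 1
    return float(onsets[max(i, 0)])


def transient_duration(
    aligned: AlignedResponses,
    baseline: tuple[float, float] = (2.0, 2.7),
    alpha: float = 0.01,
    min_transitions: int = 10,
    grace_s: float = 0.25,
) -> dict:
    """Per-electrode, per-condition duration (ms) of the post-transition
    transient.

    Per frame from the transition onward, a paired t-test across
    transitions compares the response with that transition's
    baseline-window mean; p-values are BH-FDR corrected across frames. The
    duration is the end time of the initial contiguous significant run,
    whose first significant frame may fall anywhere within ``grace_s``
    after the transition (responses lag the stimulus by the neural
    latency); 0 if no frame within the grace period is significant.

    Returns condition -> array of durations (electrodes,).
    """
    w0, w1 = aligned.window_s
    if baseline[0] < DA_WINDOW_AI[1]:
        raise ValueError("baseline window overlaps the during-adaptation window")
    fr = aligned.frame_rate
    f_zero = int(round(-w0 * fr))
    b0 = f_zero + int(round(baseline[0] * fr))
    b1 = f_zero + int(round(baseline[1] * fr))
    out = {}
    for cond, tens in aligned.tensors.items():
        n_tr, n_el, n_fr = tens.shape
        if n_tr < min_transitions:
            raise ValueError(f"condition {cond}: {n_tr} transitions < {min_transitions}")
        base = tens[:, :, b0:b1].mean(axis=2)  # transitions x electrodes
        durs = np.zeros(n_el)
        post = tens[:, :, f_zero:]
        for e in range(n_el):
            pv = np.array([
                paired_t(post[:, e, u], base[:, e])[1] for u in range(post.shape[2])
            ])
            pv = np.where(np.isnan(pv), 1.0, pv)
            rej = fdr_bh(pv, alpha)
            grace = int(round(grace_s * fr))
            sig = np.nonzero(rej[: grace + 1])[0]
            if sig.size == 0:
                durs[e] = 0.0
                continue
            run = int(sig[0])
            while run < rej.size and rej[run]:
                run += 1
            durs[e] = run * 1000.0 / fr
        out[cond] = durs
    return out


@dataclass
class AdaptationTable:
    """Electrodes x 4-condition adaptation indices (raw t-values and,
    after :func:`normalize_ai`, the min-subtracted sum-normalized rows)."""

    raw: np.ndarray  # electrodes x 4 (CONDITIONS order), NaN = undefined
    condition_order: tuple = CONDITIONS
    norm: np.ndarray | None = None
    non_adaptive: np.ndarray | None = None  # flagged rows (after normalize)
    electrode_ids: list = field(default_factory=list)
    da_window: tuple = DA_WINDOW_AI
    aa_window: tuple = AA_WINDOW_AI
    # per-transition DA-AA mean differences per condition: cond -> (K x E);
    # kept for run-to-run comparison tests
    diffs: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        cols = {f"ai_{c}": self.raw[:, j] for j, c in enumerate(self.condition_order)}
        if self.norm is not None:
            cols.update({f"norm_ai_{c}": self.norm[:, j]
                         for j, c in enumerate(self.condition_order)})
            cols["non_adaptive"] = self.non_adaptive
        ids = self.electrode_ids or [f"e{i:03d}" for i in range(self.raw.shape[0])]
        return pd.DataFrame(cols, index=pd.Index(ids, name="electrode_id"))


def adaptation_index(
    rec: NeuralRecording,
    schedule: TransitionSchedule,
    da: tuple[float, float] = DA_WINDOW_AI,
    aa: tuple[float, float] = AA_WINDOW_AI,
) -> AdaptationTable:
    """Raw adaptation indices: per electrode and condition, the paired-t
    value of DA-window vs AA-window mean responses across transitions into
    that condition. Degenerate (zero within-pair variance) cells are NaN."""
    fr = rec.fs
    aligned = align_to_transitions(rec, schedule, window_s=(0.0, max(da[1], aa[1])))
    n_el = rec.n_electrodes
    raw = np.full((n_el, len(CONDITIONS)), np.nan)
    diffs = {}
    for j, cond in enumerate(CONDITIONS):
        if cond not in aligned.tensors:
            continue
        tens = aligned.tensors[cond]
        if tens.shape[0] < 2:
            continue
        i_da = slice(int(round(da[0] * fr)), int(round(da[1] * fr)))
        i_aa = slice(int(round(aa[0] * fr)), int(round(aa[1] * fr)))
        da_m = tens[:, :, i_da].mean(axis=2)
        aa_m = tens[:, :, i_aa].mean(axis=2)
        diffs[cond] = da_m - aa_m
        for e in range(n_el):
            raw[e, j] = paired_t(da_m[:, e], aa_m[:, e])[0]
    return AdaptationTable(raw=raw, electrode_ids=list(rec.electrode_ids),
                           da_window=da, aa_window=aa, diffs=diffs)


def normalize_ai(table: AdaptationTable) -> AdaptationTable:
    """Min-subtract then sum-divide per electrode row; all-zero shifted
    rows (equal raw AIs) and rows with undefined entries are flagged
    non-adaptive instead of normalized."""
    raw = table.raw
    n = raw.shape[0]
    norm = np.full_like(raw, np.nan)
    flag = np.zeros(n, dtype=bool)
    for e in range(n):
        row = raw[e]
        if not np.all(np.isfinite(row)):
            flag[e] = True
            continue
        shifted = row - row.min()
        s = shifted.sum()
        if s == 0:
            flag[e] = True
            continue
        norm[e] = shifted / s
    table.norm = norm
    table.non_adaptive = flag
    return table


@dataclass
class ClusterResult:
    labels: np.ndarray  # k-cut labels (1..k), 0 for invalid rows
    tier: np.ndarray  # 2-cut labels (1..2), 0 for invalid rows
    dendrogram_order: np.ndarray  # indices of valid electrodes, display order
    linkage_matrix: np.ndarray
    valid: np.ndarray


def cluster_sites(table: AdaptationTable, linkage: str = "ward", k: int = 5) -> ClusterResult:
    """Hierarchical clustering of normalized AI rows (Euclidean distance).

    ``linkage="ward"`` (minimum variance) for grouping, ``"upgma"``
    (average linkage) for display ordering. Returns a k-cut labelling and
    the top-two "tier" cut. Non-adaptive/invalid rows get label 0.
    """
    if table.norm is None:
        table = normalize_ai(table)
    valid = ~table.non_adaptive
    X = table.norm[valid]
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} valid electrodes")
    method = {"ward": "ward", "upgma": "average"}.get(linkage)
    if method is None:
        raise ValueError("linkage must be 'ward' or 'upgma'")
    Z = _hier.linkage(X, method=method, metric="euclidean")
    sub_labels = _hier.fcluster(Z, k, criterion="maxclust")
    sub_tier = _hier.fcluster(Z, 2, criterion="maxclust")
    order = _hier.leaves_list(Z)
    n = table.raw.shape[0]
    labels = np.zeros(n, dtype=int)
    tier = np.zeros(n, dtype=int)
    labels[valid] = sub_labels
    tier[valid] = sub_tier
    return ClusterResult(labels, tier, np.nonzero(valid)[0][order], Z, valid)


def predict_ai(table: AdaptationTable, features, alpha_cond: float = 1e8) -> dict:
    """OLS prediction of normalized AIs from standardized tuning features.

    ``features`` is a DataFrame (or dict of arrays) with columns
    best_frequency, best_rate, speech_t (one row per electrode). Features
    are z-scored; per condition an OLS of normalized AI on the features
    yields R^2 and standardized coefficients (main effects) with t-tests.
    An ill-conditioned design (condition number > ``alpha_cond``) falls
    back to a small ridge and is flagged.

    Returns condition -> {"r2", "coef", "pvalues", "tvalues", "ridged"}.
    """
    import pandas as pd
    import statsmodels.api as sm

    if table.norm is None:
        table = normalize_ai(table)
    feats = pd.DataFrame(features).copy()
    valid = ~table.non_adaptive & np.all(np.isfinite(feats.to_numpy(float)), axis=1)
    if valid.sum() < 10:
        raise ValueError("need at least 10 valid electrodes")
    Z = feats.loc[valid].astype(float)
    Z = (Z - Z.mean()) / Z.std(ddof=0)
    X = sm.add_constant(Z.to_numpy())
    cond_number = np.linalg.cond(X)
    ridged = cond_number > alpha_cond
    out = {}
    for j, cond in enumerate(table.condition_order):
        y = table.norm[valid, j]
        if ridged:
            import warnings

            warnings.warn("collinear features: falling back to ridge")
            model = sm.OLS(y, X).fit_regularized(alpha=1e-6, L1_wt=0.0)
            coef = dict(zip(["const"] + list(Z.columns), model.params))
            out[cond] = {"r2": np.nan, "coef": coef, "pvalues": None,
                         "tvalues": None, "ridged": True}
            continue
        res = sm.OLS(y, X).fit()
        names = ["const"] + list(Z.columns)
        out[cond] = {
            "r2": float(res.rsquared),
            "coef": dict(zip(names, res.params)),
            "pvalues": dict(zip(names, res.pvalues)),
            "tvalues": dict(zip(names, res.tvalues)),
            "ridged": False,
            "results": res,
        }
    return out
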