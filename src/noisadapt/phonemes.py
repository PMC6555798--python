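"""Phoneme-aligned analysis of original and reconstructed spectrograms.

Spectrogram snippets are aligned to phoneme onsets with a fixed 200-ms
window (natural duration variation is deliberately not normalized) and
averaged per label, separately for phonemes whose onset falls in the
during-adaptation (DA) or after-adaptation (AA) interval relative to the
preceding background transition. Template-clean correlations and pairwise
dissimilarity matrices (Euclidean or correlation distance) quantify how
adaptation restores phonetic distinctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import distance as _dist

from .spectrogram import Spectrogram
from .stats import paired_t
from .synth import TransitionSchedule

__all__ = [
    "PhonemeTemplates",
    "segment_phonemes",
    "template_correlation",
    "dissimilarity_matrix",
]


@dataclass
class PhonemeTemplates:
    """Onset-aligned average spectrogram snippets per phoneme label."""

    labels: list
    templates: np.ndarray  # n_labels x window_frames x bands
    counts: np.ndarray
    interval_class: str  # "DA", "AA" or "all"
    window_ms: float
    frame_rate: float

    def flat(self) -> np.ndarray:
        return self.templates.reshape(len(self.labels), -1)


def _collect(spec, occurrences, win):
    """label -> list of snippets of ``win`` frames at each onset frame."""
    by_label = {}
    for onset_frame, label in occurrences:
        if onset_frame + win > spec.n_frames:
            continue
        by_label.setdefault(label, []).append(spec.values[onset_frame : onset_frame + win])
    return by_label


def _templates_from(by_label, cls, window_ms, fr):
    labels = sorted(by_label)
    tpl = np.stack([np.mean(by_label[lab], axis=0) for lab in labels])
    counts = np.array([len(by_label[lab]) for lab in labels])
    return PhonemeTemplates(labels, tpl, counts, cls, window_ms, fr)


def segment_phonemes(
    spec: Spectrogram,
    alignments,
    schedule: TransitionSchedule | None = None,
    da: tuple[float, float] = (0.0, 0.4),
    aa: tuple[float, float] = (2.0, 2.4),
    window_ms: float = 200.0,
):
    """Average onset-aligned snippets per label.

    ``alignments`` is a list of (onset_s, offset_s, label). With a
    ``schedule``, each phoneme is assigned to DA or AA by its onset's
    half-open offset from the preceding transition; phonemes in neither
    interval, before the first transition, or whose window crosses the
    next transition are excluded, and labels present in only one class are
    dropped with a warning. Returns ``(da_templates, aa_templates)``.
    Without a schedule, all phonemes form a single "all" class and a
    single PhonemeTemplates is returned.
    """
    fr = spec.frame_rate
    win = int(round(window_ms / 1000.0 * fr))
    if schedule is None:
        occ = [(int(np.floor(t0 * fr)), lab) for t0, _, lab in alignments]
        by_label = _collect(spec, occ, win)
        return _templates_from(by_label, "all", window_ms, fr)

    trans_times = schedule.onsets[1:]
    total = schedule.total_duration_s
    occ_da, occ_aa = [], []
    for t0, _, lab in alignments:
        i = int(np.searchsorted(trans_times, t0, side="right")) - 1
        if i < 0:
            continue  # before the first transition: undefined interval class
        delta = t0 - trans_times[i]
        nxt = trans_times[i + 1] if i + 1 < trans_times.size else total
        if t0 + window_ms / 1000.0 > nxt:
            continue  # window would straddle the next transition
        frame = int(np.floor(t0 * fr))
        if da[0] <= delta < da[1]:
            occ_da.append((frame, lab))
        elif aa[0] <= delta < aa[1]:
            occ_aa.append((frame, lab))
    by_da = _collect(spec, occ_da, win)
    by_aa = _collect(spec, occ_aa, win)
    shared = sorted(set(by_da) & set(by_aa))
    only = sorted(set(by_da) ^ set(by_aa))
    if only:
        warnings.warn(f"labels present in only one interval class excluded: {only}")
    if not shared:
        raise ValueError("no labels present in both DA and AA classes")
    return (
        _templates_from({k: by_da[k] for k in shared}, "DA", window_ms, fr),
        _templates_from({k: by_aa[k] for k in shared}, "AA", window_ms, fr),
    )


def template_correlation(recon_templates, clean_templates):
    """Per-label Pearson correlation between flattened reconstructed and
    clean templates, plus the paired t-test across labels.

    ``recon_templates`` is a (DA, AA) pair; ``clean_templates`` a single
    "all"-class PhonemeTemplates from the clean original. Labels missing
    from either side or with zero variance are excluded with a warning.

    Returns ``(labels, r_da, r_aa, (t, p))`` with the paired test on
    AA - DA.
    """
    tpl_da, tpl_aa = recon_templates
    labels = sorted(set(tpl_da.labels) & set(tpl_aa.labels) & set(clean_templates.labels))
    r_da, r_aa, kept = [], [], []
    for lab in labels:
        a = tpl_da.templates[tpl_da.labels.index(lab)].ravel()
        b = tpl_aa.templates[tpl_aa.labels.index(lab)].ravel()
        c = clean_templates.templates[clean_templates.labels.index(lab)].ravel()
        if a.std() == 0 or b.std() == 0 or c.std() == 0:
            warnings.warn(f"zero-variance template for label {lab!r} excluded")
            continue
        r_da.append(np.corrcoef(a, c)[0, 1])
        r_aa.append(np.corrcoef(b, c)[0, 1])
        kept.append(lab)
    r_da = np.array(r_da)
    r_aa = np.array(r_aa)
    return kept, r_da, r_aa, paired_t(r_aa, r_da)


def dissimilarity_matrix(templates: PhonemeTemplates, metric: str = "euclidean"):
    """Pairwise label-by-label distance matrix plus mean off-diagonal
    distance. ``metric`` is "euclidean" or "correlation" (1 - Pearson r)."""
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    X = templates.flat()
    if X.shape[0] < 2:
        raise ValueError("need at least two labels")
    D = _dist.squareform(_dist.pdist(X, metric=metric))
    n = D.shape[0]
    mean_off = float(D[~np.eye(n, dtype=bool)].mean())
    return D, mean_off
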