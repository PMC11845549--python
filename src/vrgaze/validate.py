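"""Validation battery for a classified recording.

Secondary measures that betray a bad classification without needing ground
truth: per-kind duration statistics, the saccadic main sequence (amplitude vs
peak velocity), gaze-onset-aligned velocity/dispersion matrices (velocity
should peak just before onset and stay low after), distances kept to hit
objects, and — when reference labels exist (hand labels or a simulator's
truth) — a sample-by-sample confusion matrix and an onset-shift histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import GazeRecording
from .segment_classify import (
    EventSequence,
    GAZE,
    INVALID,
    OUTLIER_GAZE,
    OUTLIER_SACCADE,
    SACCADE,
)

__all__ = [
    "ValidationReport",
    "duration_summary",
    "main_sequence",
    "onset_aligned_matrix",
    "dispersion_change",
    "gaze_distance_summary",
    "compare_labels",
    "onset_shift_histogram",
]

_CATEGORIES = ["gaze", "saccade", "invalid", "outlier"]


def _category(kind: str) -> str:
    if kind in (OUTLIER_GAZE, OUTLIER_SACCADE):
        return "outlier"
    return kind


def duration_summary(seq: EventSequence) -> pd.DataFrame:
    """Median, quartiles, mean and sd of event durations per kind."""
    rows = {}
    for kind in (GAZE, SACCADE, INVALID, OUTLIER_GAZE, OUTLIER_SACCADE):
        d = seq.durations(kind)
        if d.size == 0:
            continue
        rows[kind] = {
            "n": d.size,
            "median": float(np.median(d)),
            "q1": float(np.percentile(d, 25)),
            "q3": float(np.percentile(d, 75)),
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        }
    return pd.DataFrame(rows).T


def main_sequence(seq: EventSequence):
    """Pearson correlation of saccade amplitude with peak velocity.

    Returns ``(r, n)``; ``(None, n)`` when either variable is degenerate.
    """
    pairs = [
        (ev.amplitude, ev.peak_vel)
        for ev in seq.of_kind(SACCADE)
        if np.isfinite(ev.amplitude) and np.isfinite(ev.peak_vel)
    ]
    n = len(pairs)
    if n < 2:
        return None, n
    amp, vel = np.array(pairs).T
    if amp.std() == 0 or vel.std() == 0:
        return None, n
    r, _ = stats.pearsonr(amp, vel)
    return float(r), n


def onset_aligned_matrix(
    t_series: np.ndarray,
    values: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float] = (-0.220, 0.418),
    rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a series into onset-locked rows at frame resolution.

    Each onset is snapped to the nearest recorded sample (the underlying data
    are frame-based; no interpolation) and the row holds the series at fixed
    sample offsets spanning ``window``.  Positions outside the recording are
    NaN-padded.  Returns ``(matrix, offsets_in_samples)`` with one row per
    onset.
    """
    t = np.asarray(t_series, dtype=float)
    v = np.asarray(values, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 90.0
    offs = np.arange(int(round(window[0] * rate)), int(round(window[1] * rate)) + 1)
    mat = np.full((onsets.size, offs.size), np.nan)
    if onsets.size == 0 or t.size == 0:
        return mat, offs
    centers = np.searchsorted(t, onsets)
    centers = np.clip(centers, 0, t.size - 1)
    left = centers - 1
    use_left = (left >= 0) & (
        np.abs(t[np.clip(left, 0, None)] - onsets) < np.abs(t[centers] - onsets)
    )
    centers = np.where(use_left, left, centers)
    idx = centers[:, None] + offs[None, :]
    ok = (idx >= 0) & (idx < v.size)
    mat[ok] = v[idx[ok]]
    return mat, offs


def dispersion_change(rec: GazeRecording) -> np.ndarray:
    """Euclidean distance between consecutive hit points (world units).

    The position-domain twin of the angular velocity; absent hit points give
    NaN.  Length ``n_samples - 1``.
    """
    d = np.linalg.norm(np.diff(rec.hit_point, axis=0), axis=1)
    return d


def gaze_distance_summary(seq: EventSequence, rec: GazeRecording) -> pd.DataFrame:
    """Median/IQR of per-event mean eye-to-hit-point distance, per kind."""
    dist = np.linalg.norm(rec.eye_origin - rec.hit_point, axis=1)
    rows = {}
    for kind in (GAZE, SACCADE):
        per_event = []
        for ev in seq.of_kind(kind):
            if ev.i_on < 0:
                continue
            d = dist[ev.i_on : ev.i_off + 1]
            d = d[np.isfinite(d)]
            if d.size:
                per_event.append(d.mean())
        if not per_event:
            continue
        arr = np.array(per_event)
        rows[kind] = {
            "n": arr.size,
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }
    return pd.DataFrame(rows).T


def compare_labels(
    pred_seq: EventSequence,
    ref_seq: EventSequence,
    rec: GazeRecording,
) -> pd.DataFrame:
    """Sample-by-sample confusion matrix of predicted vs reference kinds.

    Rows are predicted categories, columns reference categories, over
    {gaze, saccade, invalid, outlier}; entries sum to the sample count.
    """
    for seq in (pred_seq, ref_seq):
        if not seq.events:
            raise DataError("cannot compare an empty event sequence")
        if seq.events[0].t_on > rec.t[0] + 1e-9 or seq.events[-1].t_off < rec.t[-1] - 1e-9:
            raise DataError("event sequence does not cover the recording timeline")
    pred = np.array([_category(k) for k in pred_seq.label_at(rec.t)])
    ref = np.array([_category(k) for k in ref_seq.label_at(rec.t)])
    mat = pd.DataFrame(
        0, index=_CATEGORIES, columns=_CATEGORIES, dtype=int
    )
    for p, r in zip(pred, ref):
        mat.loc[p, r] += 1
    return mat


def onset_shift_histogram(
    pred_onsets: np.ndarray,
    ref_onsets: np.ndarray,
    max_shift: float = 0.110,
    rate: float = 90.0,
):
    """Histogram of predicted-vs-reference gaze onset shifts, in samples.

    Each predicted onset is matched to a reference onset within
    ``±max_shift`` by greedy nearest-neighbour without replacement (smallest
    absolute shift first), preventing many-to-one inflation.  A predicted
    onset with equally near references in both directions contributes half a
    count to each signed bin.  Returns ``(bin_offsets, counts, unmatched)``
    where ``bin_offsets`` are signed shifts in eye-tracking samples and
    ``counts`` may be half-integral.
    """
    pred = np.sort(np.asarray(pred_onsets, dtype=float))
    ref = np.sort(np.asarray(ref_onsets, dtype=float))
    kmax = int(round(max_shift * rate))
    bins = np.arange(-kmax, kmax + 1)
    counts = np.zeros(bins.size)
    if pred.size == 0:
        return bins, counts, 0

    # candidate pairs within the matching window, nearest first
    cands = []
    for i, p in enumerate(pred):
        j0 = np.searchsorted(ref, p - max_shift, "left")
        j1 = np.searchsorted(ref, p + max_shift, "right")
        for j in range(j0, j1):
            shift = p - ref[j]
            cands.append((abs(shift), shift, i, j))
    cands.sort(key=lambda c: (c[0], c[2], c[3]))

    used_pred = np.zeros(pred.size, dtype=bool)
    used_ref = np.zeros(ref.size, dtype=bool)
    matched = 0
    n_c = len(cands)
    ci = 0
    while ci < n_c:
        dist, shift, i, j = cands[ci]
        if used_pred[i] or used_ref[j]:
            ci += 1
            continue
        # exact two-sided tie: the next candidate is the same prediction at
        # the same absolute shift on the other side
        tie = None
        for cj in range(ci + 1, n_c):
            d2, s2, i2, j2 = cands[cj]
            if d2 > dist + 1e-12:
                break
            if i2 == i and not used_ref[j2] and abs(s2 + shift) < 1e-12:
                tie = (s2, j2)
                break
        k = int(np.rint(shift * rate))
        if tie is not None:
            k2 = int(np.rint(tie[0] * rate))
            counts[np.searchsorted(bins, k)] += 0.5
            counts[np.searchsorted(bins, k2)] += 0.5
            used_ref[tie[1]] = True
        else:
            counts[np.searchsorted(bins, k)] += 1.0
        used_pred[i] = True
        used_ref[j] = True
        matched += 1
        ci += 1
    unmatched = int(pred.size - matched)
    return bins, counts, unmatched


@dataclass
class ValidationReport:
    """Bundle of the validation battery's outputs for one recording."""

    duration_stats: pd.DataFrame | None = None
    main_sequence_r: float | None = None
    main_sequence_n: int = 0
    distance_stats: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    shift_bins: np.ndarray | None = None
    shift_counts: np.ndarray | None = None
    shift_unmatched: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_classification(
        cls,
        seq: EventSequence,
        rec: GazeRecording,
        ref_seq: EventSequence | None = None,
        *,
        max_shift: float = 0.110,
    ) -> "ValidationReport":
        r, n = main_sequence(seq)
        report = cls(
            duration_stats=duration_summary(seq),
            main_sequence_r=r,
            main_sequence_n=n,
            distance_stats=gaze_distance_summary(seq, rec),
        )
        if ref_seq is not None:
            report.confusion = compare_labels(seq, ref_seq, rec)
            bins, counts, unmatched = onset_shift_histogram(
                seq.gaze_onsets(eeg_usable_only=False),
                ref_seq.gaze_onsets(eeg_usable_only=False),
                max_shift=max_shift,
                rate=rec.nominal_rate,
            )
            report.shift_bins = bins
            report.shift_counts = counts
            report.shift_unmatched = unmatched
        return report

    @property
    def agreement(self) -> float | None:
        """Fraction of samples on the confusion-matrix diagonal."""
        if self.confusion is None:
            return None
        total = self.confusion.to_numpy().sum()
        return float(np.trace(self.confusion.to_numpy()) / total) if total else None

    def to_dict(self) -> dict:
        out: dict = {"extras": dict(self.extras)}
        if self.duration_stats is not None:
            out["duration_stats"] = self.duration_stats.to_dict()
        out["main_sequence"] = {"r": self.main_sequence_r, "n": self.main_sequence_n}
        if self.distance_stats is not None:
            out["distance_stats"] = self.distance_stats.to_dict()
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict()
            out["agreement"] = self.agreement
        if self.shift_bins is not None:
            out["onset_shift"] = {
                "bins_samples": self.shift_bins.tolist(),
                "counts": self.shift_counts.tolist(),
                "unmatched": self.shift_unmatched,
            }
        return out
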