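"""Adaptive-threshold classification of the velocity stream into events.

A single global velocity threshold over a 30-minute free-viewing recording
only finds the very largest saccades, because noise levels vary over time.
The remedy is to segment the recording and compute a separate robust
threshold — median + k * MAD of the segment's velocities — per segment.  Two
segmentations are offered:

* ``data_driven`` — suprathreshold velocity runs (candidate saccades under
  the global threshold) are ranked by their summed velocity and the top
  ``round(target_rate * duration)`` runs become segment boundaries, placed at
  each run's peak-velocity sample, yielding an average boundary frequency of
  ``target_rate`` (default 2 Hz) over the recording.
* ``fixed_10s`` — boundaries every 10 s.

Within each segment, intervals above the segment threshold are labelled
saccade, the rest gaze (fixations and smooth pursuit pooled); invalid
intervals are labelled invalid.  Event repair then merges biologically
implausible short events into their predecessor, flags implausibly long
events via a pooled 3.5-MAD rule, assigns each gaze the modal hit object, and
rejects events overlapping non-interpolated invalid data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GazeRecording, Provenance
from .kinematics import VelocitySeries, saccade_amplitude

__all__ = [
    "SegmentSet",
    "OculomotorEvent",
    "EventSequence",
    "mad_threshold",
    "data_driven_boundaries",
    "fixed_boundaries",
    "classify_samples",
    "build_events",
    "merge_short_events",
    "reject_long_outliers",
    "assign_gaze_object",
    "reject_invalid_overlap",
    "attach_gaze_centroids",
    "attach_saccade_amplitudes",
]

GAZE = "gaze"
SACCADE = "saccade"
INVALID = "invalid"
OUTLIER_GAZE = "outlier_gaze"
OUTLIER_SACCADE = "outlier_saccade"

_LABEL_CODES = {GAZE: 0, SACCADE: 1, INVALID: 2}


@dataclass
class SegmentSet:
    """Ordered boundary timestamps partitioning a recording."""

    boundaries: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size > 1 and not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")

    def __len__(self) -> int:
        return int(self.boundaries.size)

    def segment_of(self, t: np.ndarray) -> np.ndarray:
        """Index of the segment containing each timestamp."""
        return np.searchsorted(self.boundaries, np.asarray(t, dtype=float), "right")


@dataclass
class OculomotorEvent:
    """One labelled gaze/saccade/invalid/outlier interval."""

    kind: str
    t_on: float
    t_off: float
    peak_vel: float = float("nan")
    amplitude: float = float("nan")
    centroid: np.ndarray | None = None
    hit_object: str | None = None
    i_on: int = -1   # inclusive sample index range in the source recording
    i_off: int = -1
    eeg_ok: bool = True  # False when the onset sits on an inserted timestamp

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class EventSequence:
    """Ordered, non-overlapping events tiling the classified span."""

    events: list[OculomotorEvent] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, kind: str) -> list[OculomotorEvent]:
        return [ev for ev in self.events if ev.kind == kind]

    def durations(self, kind: str) -> np.ndarray:
        return np.array([ev.duration for ev in self.of_kind(kind)])

    def gaze_onsets(self, *, eeg_usable_only: bool = True) -> np.ndarray:
        """Gaze onset times; optionally only those usable as EEG events."""
        return np.array(
            [
                ev.t_on
                for ev in self.of_kind(GAZE)
                if ev.eeg_ok or not eeg_usable_only
            ]
        )

    def label_at(self, t: np.ndarray) -> np.ndarray:
        """Event kind covering each timestamp (half-open [t_on, t_off))."""
        t = np.asarray(t, dtype=float)
        onsets = np.array([ev.t_on for ev in self.events])
        idx = np.clip(np.searchsorted(onsets, t, "right") - 1, 0, len(self.events) - 1)
        return np.array([self.events[i].kind for i in idx], dtype=object)


def mad_threshold(velocities: np.ndarray, k: float = 3.0) -> float | None:
    """Robust adaptive velocity threshold: median + k * MAD.

    Returns ``None`` for fewer than 3 finite values, in which case the caller
    falls back to the global threshold.
    """
    v = np.asarray(velocities, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        return None
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med + k * mad


def _suprathreshold_runs(vs: VelocitySeries, thr: float) -> list[tuple[int, int]]:
    above = vs.valid & np.isfinite(vs.w) & (vs.w > thr)
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def data_driven_boundaries(
    vs: VelocitySeries,
    k: float = 3.0,
    target_rate: float = 2.0,
) -> SegmentSet:
    """Segment boundaries at the biggest velocity peaks (candidate saccades).

    Suprathreshold runs under the global MAD threshold are scored by their
    summed velocity; the top ``round(target_rate * duration)`` runs each
    contribute one boundary at their peak-velocity sample.  Fewer runs than
    that simply all become boundaries.
    """
    thr = mad_threshold(vs.valid_values(), k)
    if thr is None:
        return SegmentSet(boundaries=np.empty(0), method="data_driven")
    runs = _suprathreshold_runs(vs, thr)
    if not runs:
        return SegmentSet(boundaries=np.empty(0), method="data_driven")
    scores = np.array([vs.w[i0 : i1 + 1].sum() for i0, i1 in runs])
    n_target = int(round(target_rate * vs.duration))
    order = np.argsort(-scores, kind="stable")[: max(n_target, 0)]
    peaks = []
    for ri in order:
        i0, i1 = runs[ri]
        peaks.append(vs.t[i0 + int(np.argmax(vs.w[i0 : i1 + 1]))])
    return SegmentSet(boundaries=np.sort(np.array(peaks)), method="data_driven")


def fixed_boundaries(rec_or_vs, interval: float = 10.0) -> SegmentSet:
    """Boundaries every ``interval`` seconds from the first timestamp."""
    t = rec_or_vs.t
    t0 = float(t[0])
    duration = (
        rec_or_vs.duration
        if hasattr(rec_or_vs, "duration")
        else float(t[-1] - t0)
    )
    n = int(np.floor(duration / interval))
    return SegmentSet(
        boundaries=t0 + interval * np.arange(1, n + 1), method="fixed_10s"
    )


def classify_samples(
    vs: VelocitySeries,
    segments: SegmentSet,
    k: float = 3.0,
):
    """Label every velocity interval gaze/saccade/invalid per-segment.

    Returns ``(labels, thresholds)`` where ``labels`` is an object array over
    intervals and ``thresholds`` the per-segment threshold actually used
    (segments with fewer than 3 valid intervals inherit the global one).
    """
    labels = np.full(len(vs), INVALID, dtype=object)
    global_thr = mad_threshold(vs.valid_values(), k)
    seg_idx = segments.segment_of(vs.t)
    n_seg = len(segments) + 1
    thresholds = np.full(n_seg, np.nan)
    for s in range(n_seg):
        in_seg = seg_idx == s
        use = in_seg & vs.valid & np.isfinite(vs.w)
        thr = mad_threshold(vs.w[use], k)
        if thr is None:
            thr = global_thr
        if thr is None:
            continue  # recording too short for any threshold; stays invalid
        thresholds[s] = thr
        labels[use & (vs.w > thr)] = SACCADE
        labels[use & (vs.w <= thr)] = GAZE
    return labels, thresholds


def build_events(
    labels: np.ndarray,
    rec: GazeRecording,
    vs: VelocitySeries | None = None,
) -> EventSequence:
    """Turn per-interval labels into sample-attributed events tiling the span.

    Interval ``i`` describes the motion between samples ``i`` and ``i+1``, so
    interval labels must first be attributed to samples.  Interior samples
    flanked by two same-label intervals take that label; at a transition the
    shared sample is stationary on one side, so it goes to the gaze if either
    neighbour is a gaze, else to the later interval's label.  (In particular
    a sample counts as in-flight only when both its arrival and departure
    intervals are suprathreshold — the straddling intervals at a saccade's
    edges do not drag the last/first stationary sample into it.)  Maximal
    same-label sample runs then become events; a saccade's peak velocity is
    taken over the run's intervals including the flanking motion intervals.
    """
    n_int = len(labels)
    n_s = n_int + 1
    slab = np.empty(n_s, dtype=object)
    slab[0] = labels[0]
    slab[-1] = labels[-1]
    if n_int > 1:
        a, b = labels[:-1], labels[1:]
        same = a == b
        either_gaze = (a == GAZE) | (b == GAZE)
        slab[1:-1] = np.where(same, a, np.where(either_gaze, GAZE, b))

    period = 1.0 / rec.nominal_rate
    events: list[OculomotorEvent] = []
    i = 0
    while i < n_s:
        j = i
        while j + 1 < n_s and slab[j + 1] == slab[i]:
            j += 1
        t_off = float(rec.t[j + 1]) if j + 1 < n_s else float(rec.t[j] + period)
        peak = float("nan")
        if vs is not None:
            seg = vs.w[max(i - 1, 0) : min(j + 1, n_int)]
            finite = seg[np.isfinite(seg)]
            if finite.size:
                peak = float(finite.max())
        events.append(
            OculomotorEvent(
                kind=str(slab[i]),
                t_on=float(rec.t[i]),
                t_off=t_off,
                peak_vel=peak,
                i_on=i,
                i_off=j,
            )
        )
        i = j + 1
    return EventSequence(events=events, source=rec.meta.get("source", ""))


def merge_short_events(
    seq: EventSequence,
    min_saccade: float = 0.020,
    min_gaze: float = 0.040,
) -> EventSequence:
    """Absorb biologically implausible short events into their neighbour.

    A saccade shorter than 20 ms or a gaze shorter than 40 ms is merged into
    the immediately preceding event, which keeps its kind and extends its
    offset; a too-short *first* event is absorbed forward into the following
    event.  Merging can create new same-kind adjacencies (gaze | short
    saccade | gaze collapses to one gaze), so same-kind neighbours are fused
    and the scan is iterated to a fixed point.
    """
    events = [
        OculomotorEvent(
            kind=ev.kind,
            t_on=ev.t_on,
            t_off=ev.t_off,
            peak_vel=ev.peak_vel,
            amplitude=ev.amplitude,
            centroid=ev.centroid,
            hit_object=ev.hit_object,
            i_on=ev.i_on,
            i_off=ev.i_off,
            eeg_ok=ev.eeg_ok,
        )
        for ev in seq.events
    ]

    def fuse(dst: OculomotorEvent, src: OculomotorEvent) -> None:
        dst.t_on = min(dst.t_on, src.t_on)
        dst.t_off = max(dst.t_off, src.t_off)
        if dst.i_on >= 0 and src.i_on >= 0:
            dst.i_on = min(dst.i_on, src.i_on)
            dst.i_off = max(dst.i_off, src.i_off)
        if np.isnan(dst.peak_vel):
            dst.peak_vel = src.peak_vel
        elif not np.isnan(src.peak_vel):
            dst.peak_vel = max(dst.peak_vel, src.peak_vel)

    def too_short(ev: OculomotorEvent) -> bool:
        return (ev.kind == SACCADE and ev.duration < min_saccade) or (
            ev.kind == GAZE and ev.duration < min_gaze
        )

    changed = True
    while changed and len(events) > 1:
        changed = False
        out: list[OculomotorEvent] = []
        for ev in events:
            if out and ev.kind == out[-1].kind:
                fuse(out[-1], ev)  # same-kind neighbours always fuse
                changed = True
            elif out and too_short(ev):
                fuse(out[-1], ev)  # absorbed backward; predecessor keeps kind
                changed = True
            else:
                out.append(ev)
        events = out
        if len(events) > 1 and too_short(events[0]):
            # a too-short leading event has no predecessor; absorb it forward
            fuse(events[1], events[0])
            del events[0]
            changed = True
    return EventSequence(events=events, source=seq.source)


def reject_long_outliers(
    seqs: EventSequence | list[EventSequence],
    multiplier: float = 3.5,
) -> EventSequence | list[EventSequence]:
    """Flag implausibly long events via a pooled median + 3.5 MAD rule.

    Durations are pooled per kind across all provided sequences (across
    subjects when several are given); events beyond the threshold are
    relabelled ``outlier_gaze``/``outlier_saccade``.  The rule is one-sided —
    only too-long events are outliers.  With a degenerate MAD of zero,
    nothing is flagged when all durations are equal; otherwise anything
    strictly above the median is.
    """
    single = isinstance(seqs, EventSequence)
    pool = [seqs] if single else list(seqs)
    for kind, outlier_kind in ((GAZE, OUTLIER_GAZE), (SACCADE, OUTLIER_SACCADE)):
        durations = np.concatenate(
            [seq.durations(kind) for seq in pool]
            or [np.empty(0)]
        )
        if durations.size == 0:
            continue
        med = float(np.median(durations))
        mad = float(np.median(np.abs(durations - med)))
        # durations equal up to float noise: nothing to flag
        if mad <= 1e-9 * max(med, 1e-12) and np.allclose(
            durations, durations[0], rtol=1e-9, atol=1e-12
        ):
            continue
        cutoff = med + multiplier * mad if mad > 0 else med * (1 + 1e-9)
        for seq in pool:
            for ev in seq.of_kind(kind):
                if ev.duration > cutoff:
                    ev.kind = outlier_kind
    return pool[0] if single else pool


def assign_gaze_object(seq: EventSequence, rec: GazeRecording) -> EventSequence:
    """Assign each gaze event the modal hit object among its samples.

    Ties are broken by earliest first occurrence within the event; events
    whose samples all missed the scene keep no object.
    """
    for ev in seq.of_kind(GAZE):
        if ev.i_on < 0:
            continue
        counts: dict[str, int] = {}
        for obj in rec.hit_object[ev.i_on : ev.i_off + 1]:
            if obj is not None:
                counts[obj] = counts.get(obj, 0) + 1
        if counts:
            # dict preserves first-occurrence order, so max() on counts alone
            # returns the earliest-seen object among tied counts
            ev.hit_object = max(counts, key=counts.get)
    return seq


def reject_invalid_overlap(seq: EventSequence, rec: GazeRecording) -> EventSequence:
    """Reject events overlapping invalid data; disqualify inserted onsets.

    Events containing any sample that is still invalid (interpolated samples
    count as valid) are relabelled invalid.  Gaze events whose onset sample
    is an inserted timestamp are kept but marked unusable as EEG events,
    since their onset time is not a measured frame.
    """
    for ev in seq.events:
        if ev.i_on < 0 or ev.kind == INVALID:
            continue
        if not np.all(rec.valid[ev.i_on : ev.i_off + 1]):
            ev.kind = INVALID
    for ev in seq.of_kind(GAZE):
        if ev.i_on >= 0 and rec.provenance[ev.i_on] == Provenance.TIMESTAMP_INTERPOLATED:
            ev.eeg_ok = False
    return seq


def attach_gaze_centroids(seq: EventSequence, rec: GazeRecording) -> EventSequence:
    """Set each gaze event's centroid to the mean of its hit points."""
    for ev in seq.events:
        if ev.kind != GAZE or ev.i_on < 0:
            continue
        pts = rec.hit_point[ev.i_on : ev.i_off + 1]
        pts = pts[~np.any(np.isnan(pts), axis=1)]
        if pts.shape[0]:
            ev.centroid = pts.mean(axis=0)
    return seq


def attach_saccade_amplitudes(seq: EventSequence, rec: GazeRecording) -> EventSequence:
    """Compute amplitudes for saccades flanked by gazes with centroids."""
    events = seq.events
    for idx, ev in enumerate(events):
        if ev.kind != SACCADE:
            continue
        prev_c = next_c = None
        if idx > 0 and events[idx - 1].kind == GAZE:
            prev_c = events[idx - 1].centroid
        if idx + 1 < len(events) and events[idx + 1].kind == GAZE:
            next_c = events[idx + 1].centroid
        if prev_c is None or next_c is None or ev.i_on < 0:
            continue
        ev.amplitude = saccade_amplitude(
            prev_c, next_c, rec.eye_origin[ev.i_on], rec.eye_dir[ev.i_on]
        )
    return seq
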