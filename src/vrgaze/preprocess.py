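"""Validity handling and filtering of the raw gaze stream.

Order of operations (before any velocity is computed):

1. :func:`expand_invalid` — pad substantial invalid runs (blinks, tracking
   loss) because the samples immediately flanking a blink are unreliable.
2. :func:`interpolate_short_gaps` — linearly fill invalid runs shorter than a
   cutoff, on the rationale that an observer is unlikely to fixate elsewhere
   and return within that time.
3. :func:`median_filter5` — 5-point median filtering of observer positions
   and hit points, which removes single outlying samples without low-passing
   saccade onsets/offsets the way a moving average would.

Direction vectors are deliberately not median-filtered; they are renormalised
and used raw by the kinematics.
"""

from __future__ import annotations

import numpy as np

from .io import GazeRecording, Provenance

__all__ = [
    "expand_invalid",
    "interpolate_short_gaps",
    "median_filter5",
    "preprocess_recording",
    "invalid_runs",
]


def invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as (first, last) inclusive indices."""
    inv = ~np.asarray(valid, dtype=bool)
    if not inv.any():
        return []
    padded = np.concatenate(([False], inv, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _run_duration(rec: GazeRecording, i0: int, i1: int) -> float:
    # a k-sample run covers roughly k frame periods, not k-1 stamp gaps
    return float(rec.t[i1] - rec.t[i0]) + 1.0 / rec.nominal_rate


def expand_invalid(
    rec: GazeRecording,
    *,
    min_invalid: float = 0.020,
    pad: float = 0.023,
) -> GazeRecording:
    """Pad invalid runs longer than ``min_invalid`` by ``pad`` seconds.

    Samples whose timestamp lies within ``pad`` before the run's first sample
    or after its last sample are marked invalid.  Shorter runs (single lost
    frames) are left untouched.  Measured values are never altered — only
    validity flags change.
    """
    out = rec.copy()
    for i0, i1 in invalid_runs(rec.valid):
        if _run_duration(rec, i0, i1) > min_invalid:
            mask = (rec.t >= rec.t[i0] - pad) & (rec.t <= rec.t[i1] + pad)
            out.valid[mask] = False
    return out


def interpolate_short_gaps(
    rec: GazeRecording, max_gap: float = 0.250
) -> GazeRecording:
    """Linearly fill invalid runs strictly shorter than ``max_gap`` seconds.

    Positions, directions and hit points are interpolated in time between the
    flanking valid samples; directions are renormalised afterwards.  The hit
    object is categorical and is left absent.  Runs touching the recording
    edge are never extrapolated.  Filled samples become valid; originally
    measured ones are flagged ``INTERPOLATED`` while inserted timestamps keep
    their ``TIMESTAMP_INTERPOLATED`` provenance (they remain disqualified as
    event onsets downstream).
    """
    out = rec.copy()
    n_filled = 0
    for i0, i1 in invalid_runs(rec.valid):
        if i0 == 0 or i1 == len(rec) - 1:
            continue
        if _run_duration(rec, i0, i1) >= max_gap:
            continue
        a, b = i0 - 1, i1 + 1  # flanking valid samples
        w = (rec.t[i0 : i1 + 1] - rec.t[a]) / (rec.t[b] - rec.t[a])
        for name in ("eye_origin", "eye_dir", "head_pos", "head_dir"):
            arr = getattr(out, name)
            arr[i0 : i1 + 1] = arr[a] + w[:, None] * (arr[b] - arr[a])
        hp = out.hit_point
        if not (np.any(np.isnan(hp[a])) or np.any(np.isnan(hp[b]))):
            hp[i0 : i1 + 1] = hp[a] + w[:, None] * (hp[b] - hp[a])
        out.hit_object[i0 : i1 + 1] = None
        out.valid[i0 : i1 + 1] = True
        measured = out.provenance[i0 : i1 + 1] != Provenance.TIMESTAMP_INTERPOLATED
        out.provenance[i0 : i1 + 1][measured] = Provenance.INTERPOLATED
        n_filled += int(i1 - i0 + 1)
    for name in ("eye_dir", "head_dir"):
        arr = getattr(out, name)
        norms = np.linalg.norm(arr, axis=1)
        ok = norms > 0
        arr[ok] /= norms[ok, None]
    out.meta["interpolated_fraction"] = n_filled / max(len(rec), 1)
    return out


def median_filter5(series: np.ndarray) -> np.ndarray:
    """5-point running median with symmetrically shrinking edge windows.

    The window shrinks to 3 points one sample from each edge and to a
    passthrough at the edges themselves.  NaNs (absent values) propagate to
    the output at their own position but are ignored inside neighbouring
    windows.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 3:
        return x.copy()
    import warnings

    out = np.empty_like(x)
    out[0] = x[0]
    out[-1] = x[-1]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        if n >= 5:
            win = np.lib.stride_tricks.sliding_window_view(x, 5, axis=0)
            out[2 : n - 2] = np.nanmedian(win, axis=-1)
            out[1] = np.nanmedian(x[:3], axis=0)
            out[-2] = np.nanmedian(x[-3:], axis=0)
        else:
            for i in range(1, n - 1):
                out[i] = np.nanmedian(x[i - 1 : i + 2], axis=0)
    out[np.isnan(x)] = np.nan
    return out


def preprocess_recording(
    rec: GazeRecording,
    *,
    min_invalid: float = 0.020,
    pad: float = 0.023,
    max_gap: float = 0.250,
    median_filter: bool = True,
) -> GazeRecording:
    """Full preprocessing chain: expand, interpolate, median-filter."""
    out = expand_invalid(rec, min_invalid=min_invalid, pad=pad)
    out = interpolate_short_gaps(out, max_gap=max_gap)
    if median_filter:
        for name in ("eye_origin", "head_pos", "hit_point"):
            arr = getattr(out, name)
            for j in range(3):
                arr[:, j] = median_filter5(arr[:, j])
    return out
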