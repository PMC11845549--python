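"""Alignment of the eye-tracking clock to the EEG clock.

Two independently clocked acquisition chains (the VR engine writing gaze
samples, the EEG amplifier writing voltages) drift apart slowly but roughly
linearly over a recording.  The correction used here needs no shared content:
the constant offset is removed by subtracting the first EEG timestamp, and the
residual drift — the difference between the two streams' total durations — is
spread linearly across the eye-tracking timeline.  Dropped engine frames are
first patched by inserting evenly spaced timestamps so the drift is added on a
regular time base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .io import GazeRecording, Provenance

__all__ = [
    "ClockModel",
    "regularize_et_timestamps",
    "estimate_clock_drift",
    "to_eeg_time",
    "map_onsets_to_eeg",
]


@dataclass
class ClockModel:
    """Affine map from the eye-tracking clock onto the EEG clock.

    The mapped time is expressed in seconds since the start of the EEG
    recording (the raw EEG start timestamp, stored in ``offset``, has already
    been subtracted).

    Parameters
    ----------
    offset : first EEG timestamp on the EEG clock (seconds).
    drift_total : EEG duration minus eye-tracking duration (seconds); signed,
        accumulated over the whole recording and spread linearly.
    t0_et, t1_et : first/last eye-tracking timestamps defining the span the
        drift is spread over.
    method : ``"endpoint"`` (duration difference) or ``"least_squares"``
        (affine fit through endpoints plus optional shared marker pairs).
    """

    offset: float
    drift_total: float
    t0_et: float
    t1_et: float
    method: str = "endpoint"
    slope: float | None = None       # least-squares fit, else derived
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.t1_et <= self.t0_et:
            raise ValueError("t1_et must exceed t0_et")
        span = self.t1_et - self.t0_et
        if self.slope is None:
            self.slope = 1.0 + self.drift_total / span
        if self.intercept is None:
            self.intercept = 0.0
        if self.slope <= 0:
            raise ValueError("clock map must be strictly increasing")


def regularize_et_timestamps(
    rec: GazeRecording, nominal_rate: float | None = None
) -> GazeRecording:
    """Fill dropped-frame gaps with evenly spaced inserted timestamps.

    Gaps exceeding 1.5x the nominal frame period are treated as dropped
    frames; the missing stamps are inserted evenly, carry no measured data,
    and are flagged ``Provenance.TIMESTAMP_INTERPOLATED`` and invalid.  Event
    onsets are never allowed on such stamps downstream.
    """
    rate = rec.nominal_rate if nominal_rate is None else nominal_rate
    if rate <= 0:
        raise ConfigError("nominal_rate must be positive")
    period = 1.0 / rate
    t = rec.t
    gaps = np.diff(t)
    drop = np.flatnonzero(gaps > 1.5 * period)
    if drop.size == 0:
        return rec.copy()

    new_t: list[np.ndarray] = []
    insert_after: list[int] = []
    counts: list[int] = []
    for i in drop:
        n_ins = int(round(gaps[i] / period)) - 1
        if n_ins < 1:
            n_ins = 1
        frac = np.arange(1, n_ins + 1) / (n_ins + 1)
        new_t.append(t[i] + frac * gaps[i])
        insert_after.append(i)
        counts.append(n_ins)

    n_old = len(rec)
    n_new = n_old + sum(counts)
    out_t = np.empty(n_new)
    inserted = np.zeros(n_new, dtype=bool)
    src = np.empty(n_new, dtype=np.intp)

    pos = 0
    prev = 0
    for stamps, i in zip(new_t, insert_after):
        block = i + 1 - prev
        out_t[pos : pos + block] = t[prev : i + 1]
        src[pos : pos + block] = np.arange(prev, i + 1)
        pos += block
        k = stamps.size
        out_t[pos : pos + k] = stamps
        inserted[pos : pos + k] = True
        src[pos : pos + k] = i  # placeholder source; values are NaN'd below
        pos += k
        prev = i + 1
    block = n_old - prev
    out_t[pos : pos + block] = t[prev:]
    src[pos : pos + block] = np.arange(prev, n_old)

    def take(arr: np.ndarray) -> np.ndarray:
        out = arr[src].copy()
        out[inserted] = np.nan
        return out

    return GazeRecording(
        t=out_t,
        eye_origin=take(rec.eye_origin),
        eye_dir=take(rec.eye_dir),
        head_pos=take(rec.head_pos),
        head_dir=take(rec.head_dir),
        hit_point=take(rec.hit_point),
        hit_object=np.where(inserted, None, rec.hit_object[src]),
        valid=np.where(inserted, False, rec.valid[src]),
        provenance=np.where(
            inserted, np.int8(Provenance.TIMESTAMP_INTERPOLATED), rec.provenance[src]
        ),
        nominal_rate=rec.nominal_rate,
        meta=dict(rec.meta, n_inserted_stamps=int(inserted.sum())),
    )


def estimate_clock_drift(
    et_times: np.ndarray,
    eeg_times: np.ndarray,
    method: str = "endpoint",
    markers: list[tuple[float, float]] | None = None,
) -> ClockModel:
    """Estimate the affine eye-tracking -> EEG clock map.

    The endpoint method matches the start and end of the two streams: the
    offset is the first EEG timestamp and the total drift is the difference of
    the two durations.  The least-squares method fits the affine map to the
    matched endpoints plus any shared ``(t_et, t_eeg)`` marker pairs, which is
    less sensitive to noise on the first/last samples.
    """
    et_times = np.asarray(et_times, dtype=float)
    eeg_times = np.asarray(eeg_times, dtype=float)
    if et_times.size < 2 or eeg_times.size < 2:
        raise DataError("both streams need at least two timestamps")
    et_span = float(et_times[-1] - et_times[0])
    eeg_span = float(eeg_times[-1] - eeg_times[0])
    if et_span <= 0 or eeg_span <= 0:
        raise DataError("stream duration must be positive")

    offset = float(eeg_times[0])
    drift_total = eeg_span - et_span
    t0, t1 = float(et_times[0]), float(et_times[-1])

    if method == "endpoint":
        return ClockModel(offset, drift_total, t0, t1, method="endpoint")
    if method == "least_squares":
        xs = [t0, t1]
        ys = [0.0, eeg_span]
        for t_et, t_eeg in markers or []:
            xs.append(float(t_et))
            ys.append(float(t_eeg) - offset)
        slope, b = np.polyfit(np.array(xs) - t0, np.array(ys), 1)
        return ClockModel(
            offset,
            drift_total=float(slope - 1.0) * (t1 - t0),
            t0_et=t0,
            t1_et=t1,
            method="least_squares",
            slope=float(slope),
            intercept=float(b),
        )
    raise ConfigError(f"unknown drift method {method!r}")


def to_eeg_time(t_et, model: ClockModel):
    """Map eye-tracking timestamps to seconds since EEG recording start."""
    t_et = np.asarray(t_et, dtype=float)
    return (t_et - model.t0_et) * model.slope + model.intercept


def map_onsets_to_eeg(
    onset_ts_et,
    model: ClockModel,
    eeg_rate: float,
    n_samples: int | None = None,
):
    """Convert event onsets on the eye-tracking clock to EEG sample indices.

    Rounds to the nearest EEG sample (ties to even).  Returns ``(indices,
    in_range)``; out-of-range onsets are flagged, not dropped, so callers can
    keep their own bookkeeping.
    """
    t_eeg = to_eeg_time(np.asarray(onset_ts_et, dtype=float), model)
    idx = np.rint(t_eeg * eeg_rate).astype(np.int64)
    in_range = idx >= 0
    if n_samples is not None:
        in_range &= idx < n_samples
    return idx, in_range


def write_clock_model(model: ClockModel, path) -> None:
    """Serialise a clock model as a small key=value text file."""
    with open(path, "w") as fh:
        for key in ("offset", "drift_total", "t0_et", "t1_et", "slope", "intercept"):
            fh.write(f"{key}={getattr(model, key)!r}\n")
        fh.write(f"method={model.method}\n")


def read_clock_model(path) -> ClockModel:
    """Read a clock model written by :func:`write_clock_model`."""
    fields: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            key, val = line.split("=", 1)
            fields[key] = val if key == "method" else float(val)
    return ClockModel(**fields)  # type: ignore[arg-type]
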