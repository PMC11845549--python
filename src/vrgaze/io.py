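"""Data model and table I/O for eye-tracking and EEG streams.

The in-memory containers are array-backed: a :class:`GazeRecording` holds one
NumPy array per field (times, eye origin, allocentric eye direction, head
position/direction, gaze-ray hit point, hit-object id, validity, provenance),
which keeps the downstream kinematics vectorised.  A :class:`GazeSample` is a
lightweight per-row view used where single-sample semantics are clearer.

Absent hit points are encoded as NaN rows (and ``None`` hit objects), never as
sentinel coordinates, so that accidental arithmetic on "no hit" is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

__all__ = [
    "Provenance",
    "GazeSample",
    "GazeRecording",
    "EEGRecording",
    "read_gaze_table",
    "write_gaze_table",
    "renormalize_directions",
    "write_events",
    "read_events",
    "read_eeg_matrix",
    "EVENT_COLUMNS",
]


class Provenance(IntEnum):
    """How a sample's values came to be."""

    MEASURED = 0
    INTERPOLATED = 1            # values filled across a short invalid run
    TIMESTAMP_INTERPOLATED = 2  # stamp inserted to fill a dropped frame


@dataclass
class GazeSample:
    """One eye-tracking sample (a row view of a :class:`GazeRecording`)."""

    t: float
    eye_origin: np.ndarray
    eye_dir: np.ndarray
    head_pos: np.ndarray
    head_dir: np.ndarray
    hit_point: np.ndarray | None = None
    hit_object: str | None = None
    valid: bool = True
    provenance: Provenance = Provenance.MEASURED


@dataclass
class GazeRecording:
    """Time-ordered 3D eye-tracking samples with validity/provenance flags.

    All per-sample fields are parallel arrays of length ``n``; 3-vectors are
    ``(n, 3)`` arrays.  ``hit_point`` rows are NaN where the gaze ray hit
    nothing; ``hit_object`` entries are ``None`` there.
    """

    t: np.ndarray
    eye_origin: np.ndarray
    eye_dir: np.ndarray
    head_pos: np.ndarray
    head_dir: np.ndarray
    hit_point: np.ndarray
    hit_object: np.ndarray
    valid: np.ndarray
    provenance: np.ndarray
    nominal_rate: float = 90.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        for name in ("eye_origin", "eye_dir", "head_pos", "head_dir", "hit_point"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            setattr(self, name, arr)
        self.hit_object = np.asarray(self.hit_object, dtype=object)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise DataError(f"timestamps not strictly increasing at sample {bad}")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def sample(self, i: int) -> GazeSample:
        hp = self.hit_point[i]
        return GazeSample(
            t=float(self.t[i]),
            eye_origin=self.eye_origin[i].copy(),
            eye_dir=self.eye_dir[i].copy(),
            head_pos=self.head_pos[i].copy(),
            head_dir=self.head_dir[i].copy(),
            hit_point=None if np.any(np.isnan(hp)) else hp.copy(),
            hit_object=self.hit_object[i],
            valid=bool(self.valid[i]),
            provenance=Provenance(int(self.provenance[i])),
        )

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            t=self.t.copy(),
            eye_origin=self.eye_origin.copy(),
            eye_dir=self.eye_dir.copy(),
            head_pos=self.head_pos.copy(),
            head_dir=self.head_dir.copy(),
            hit_point=self.hit_point.copy(),
            hit_object=self.hit_object.copy(),
            valid=self.valid.copy(),
            provenance=self.provenance.copy(),
            nominal_rate=self.nominal_rate,
            meta=dict(self.meta),
        )

    def has_hit(self) -> np.ndarray:
        """Boolean mask of samples whose gaze ray hit a surface."""
        return ~np.any(np.isnan(self.hit_point), axis=1)


@dataclass
class EEGRecording:
    """EEG as a channels x time matrix (microvolts) on its own clock."""

    data: np.ndarray
    rate: float
    start_t: float = 0.0
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} rows"
            )

    @property
    def n_times(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_times / self.rate

    def pick(self, channel: str) -> np.ndarray:
        """Return the 1-D time course of one named channel."""
        try:
            return self.data[self.channels.index(channel)]
        except ValueError:
            raise KeyError(f"no channel named {channel!r}") from None


# ---------------------------------------------------------------------------
# Gaze table I/O

_VEC_FIELDS = ("eye_origin", "eye_dir", "head_pos", "head_dir")

#: Default column map matching the tables this toolkit writes itself.
DEFAULT_COLUMN_MAP: dict[str, object] = {
    "t": "t",
    "eye_origin": ("origin_x", "origin_y", "origin_z"),
    "eye_dir": ("dir_x", "dir_y", "dir_z"),
    "head_pos": ("head_x", "head_y", "head_z"),
    "head_dir": ("head_dir_x", "head_dir_y", "head_dir_z"),
    "hit_point": ("hit_x", "hit_y", "hit_z"),
    "hit_object": "hit_object",
    "valid": "valid",
}

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


def _parse_bool(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    s = col.astype(str).str.strip().str.lower()
    out = np.empty(len(s), dtype=bool)
    for i, v in enumerate(s):
        if v in _TRUE_STRINGS:
            out[i] = True
        elif v in _FALSE_STRINGS:
            out[i] = False
        else:
            raise DataError(f"cannot parse validity value {v!r} at row {i + 1}")
    return out


def read_gaze_table(
    path,
    column_map: Mapping[str, object] | None = None,
    *,
    delimiter: str = "\t",
    nominal_rate: float = 90.0,
) -> GazeRecording:
    """Read a delimited eye-tracking sample table into a :class:`GazeRecording`.

    ``column_map`` names, for each sample field, the column (or 3-tuple of
    columns for vector fields) carrying it; the raw schema of VR recordings is
    engine-specific, so the mapping is explicit rather than guessed.  The hit
    fields and the provenance column are optional; empty hit cells parse as
    "no hit".
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep=delimiter)

    required: list[str] = []
    for fld in ("t", "valid", *(f for f in _VEC_FIELDS)):
        if fld not in cmap:
            raise SchemaError(f"column_map lacks required field {fld!r}")
        cols = cmap[fld]
        required.extend([cols] if isinstance(cols, str) else list(cols))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    n = len(df)
    t = df[cmap["t"]].to_numpy(dtype=float)
    if n > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # 1-based data row
        raise DataError(f"timestamps not strictly increasing at row {bad}")

    def vec(fld: str) -> np.ndarray:
        return df[list(cmap[fld])].to_numpy(dtype=float)

    if "hit_point" in cmap and all(c in df.columns for c in cmap["hit_point"]):
        hit_point = df[list(cmap["hit_point"])].to_numpy(dtype=float)
    else:
        hit_point = np.full((n, 3), np.nan)

    hit_object = np.full(n, None, dtype=object)
    if "hit_object" in cmap and cmap["hit_object"] in df.columns:
        raw = df[cmap["hit_object"]]
        mask = raw.notna() & (raw.astype(str).str.strip() != "")
        hit_object[mask.to_numpy()] = raw[mask].astype(str).to_numpy()
    # no hit point implies no hit object
    hit_object[np.any(np.isnan(hit_point), axis=1)] = None

    provenance = np.zeros(n, dtype=np.int8)
    if "provenance" in cmap and cmap["provenance"] in df.columns:
        provenance = df[cmap["provenance"]].to_numpy(dtype=np.int8)

    return GazeRecording(
        t=t,
        eye_origin=vec("eye_origin"),
        eye_dir=vec("eye_dir"),
        head_pos=vec("head_pos"),
        head_dir=vec("head_dir"),
        hit_point=hit_point,
        hit_object=hit_object,
        valid=_parse_bool(df[cmap["valid"]]),
        provenance=provenance,
        nominal_rate=nominal_rate,
        meta={"source": str(path)},
    )


def write_gaze_table(rec: GazeRecording, path, *, delimiter: str = "\t") -> None:
    """Write a recording in the default column layout (lossless round-trip)."""
    cols: dict[str, object] = {"t": rec.t}
    for fld, names in (
        ("eye_origin", DEFAULT_COLUMN_MAP["eye_origin"]),
        ("eye_dir", DEFAULT_COLUMN_MAP["eye_dir"]),
        ("head_pos", DEFAULT_COLUMN_MAP["head_pos"]),
        ("head_dir", DEFAULT_COLUMN_MAP["head_dir"]),
        ("hit_point", DEFAULT_COLUMN_MAP["hit_point"]),
    ):
        arr = getattr(rec, fld)
        for j, name in enumerate(names):
            cols[name] = arr[:, j]
    cols["hit_object"] = ["" if o is None else o for o in rec.hit_object]
    cols["valid"] = rec.valid.astype(int)
    cols["provenance"] = rec.provenance
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def renormalize_directions(rec: GazeRecording) -> GazeRecording:
    """Rescale eye and head direction vectors to unit norm.

    The engine-exported "normalized" vectors are not exactly unit length, so
    they are recomputed offline.  Zero-norm eye directions cannot be
    normalised; those samples are flagged invalid instead.  Idempotent.
    """
    out = rec.copy()
    for name in ("eye_dir", "head_dir"):
        arr = getattr(out, name)
        norms = np.linalg.norm(arr, axis=1)
        ok = norms > 0
        arr[ok] = arr[ok] / norms[ok, None]
        if name == "eye_dir":
            out.valid = out.valid & ok
    return out


# ---------------------------------------------------------------------------
# Event table I/O

EVENT_COLUMNS = [
    "kind",
    "t_on",
    "t_off",
    "duration_s",
    "peak_vel_dps",
    "amplitude_deg",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "hit_object",
]


def write_events(seq, path, *, delimiter: str = "\t") -> None:
    """Write an event sequence as a delimited table, one row per event."""
    rows = []
    for ev in seq.events:
        cen = ev.centroid if ev.centroid is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "kind": ev.kind,
                "t_on": ev.t_on,
                "t_off": ev.t_off,
                "duration_s": ev.duration,
                "peak_vel_dps": ev.peak_vel,
                "amplitude_deg": ev.amplitude,
                "centroid_x": cen[0],
                "centroid_y": cen[1],
                "centroid_z": cen[2],
                "hit_object": "" if ev.hit_object is None else ev.hit_object,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_events(path, *, delimiter: str = "\t"):
    """Read an event table written by :func:`write_events`."""
    from .segment_classify import EventSequence, OculomotorEvent

    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing event column(s): {', '.join(missing)}")
    events = []
    for _, row in df.iterrows():
        cen = np.array([row.centroid_x, row.centroid_y, row.centroid_z])
        obj = row.hit_object
        events.append(
            OculomotorEvent(
                kind=str(row.kind),
                t_on=float(row.t_on),
                t_off=float(row.t_off),
                peak_vel=float(row.peak_vel_dps),
                amplitude=float(row.amplitude_deg),
                centroid=None if np.all(np.isnan(cen)) else cen,
                hit_object=None if (pd.isna(obj) or obj == "") else str(obj),
            )
        )
    return EventSequence(events=events, source=str(path))


# ---------------------------------------------------------------------------
# EEG matrix I/O

def read_eeg_matrix(
    path,
    rate: float,
    start_t: float = 0.0,
    channels: Sequence[str] | None = None,
    *,
    orientation: str = "channels_rows",
    delimiter: str = "\t",
) -> EEGRecording:
    """Read a delimited numeric matrix as an :class:`EEGRecording`.

    ``orientation`` declares whether rows are channels (``channels_rows``) or
    samples (``samples_rows``).  Rate, start time, and channel names come from
    the caller (typically a side-car config), not the file.
    """
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-file notice
            data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise DataError(f"cannot parse EEG matrix {path}: {exc}") from exc
    if data.size == 0:
        raise DataError(f"EEG matrix {path} is empty")
    if orientation == "samples_rows":
        data = data.T
    elif orientation != "channels_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return EEGRecording(
        data=data,
        rate=rate,
        start_t=start_t,
        channels=list(channels) if channels is not None else [],
    )
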