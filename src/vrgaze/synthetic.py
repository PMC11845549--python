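"""Ground-truth simulator: VR scanpaths at 90 Hz and onset-locked EEG.

The generator emulates the statistical structure of a free-exploration VR
recording: an observer standing in a small walkable area of a simple
box-world scene alternates fixations (gamma-distributed durations) on scene
surfaces with saccades whose duration follows a main-sequence law in their
amplitude and whose velocity follows a raised-cosine profile.  The head
translates as a bounded random walk and its direction lazily follows the
gaze.  Samples are ray-cast against the scene to produce hit points exactly
as a game engine would.  A separate corruption stage adds direction noise,
blinks (invalid runs) and dropped frames; a separate EEG stage renders
gaze-onset-locked evoked activity, an induced oscillation whose amplitude
changes after onset, and 1/f background noise on a clock that drifts
linearly against the eye-tracking clock.

Everything is deterministic under the configured seed, and the generator
returns the true event list and the true clock map so that every downstream
stage can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .io import EEGRecording, GazeRecording
from .segment_classify import EventSequence, GAZE, INVALID, OculomotorEvent, SACCADE
from .sync import ClockModel, to_eeg_time

__all__ = [
    "SceneModel",
    "SimulationConfig",
    "GroundTruth",
    "default_scene",
    "raycast",
    "simulate_scanpath",
    "corrupt",
    "simulate_eeg",
]


@dataclass
class SceneModel:
    """A ground plane at height zero plus axis-aligned boxes (y-up)."""

    boxes: list[tuple[str, np.ndarray, np.ndarray]] = field(default_factory=list)
    walk_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (-3.0, 3.0),
        (-3.0, 3.0),
    )
    ground_id: str = "ground"

    def __post_init__(self) -> None:
        ids = [b[0] for b in self.boxes]
        if len(set(ids)) != len(ids):
            raise ConfigError("box ids must be unique")
        boxes = []
        for bid, lo, hi in self.boxes:
            lo = np.asarray(lo, dtype=float)
            hi = np.asarray(hi, dtype=float)
            if np.any(hi <= lo):
                raise ConfigError(f"degenerate box {bid!r}")
            boxes.append((bid, lo, hi))
        self.boxes = boxes


def default_scene() -> SceneModel:
    """A plaza: walkable centre ring of benches, surrounded by house fronts."""
    boxes = []
    for i in range(8):
        az = 2 * np.pi * i / 8
        cx, cz = 15.0 * np.cos(az), 15.0 * np.sin(az)
        boxes.append(
            (
                f"house_{i}",
                np.array([cx - 3.0, 0.0, cz - 3.0]),
                np.array([cx + 3.0, 6.0 + 2.0 * (i % 3), cz + 3.0]),
            )
        )
    for i in range(4):
        az = 2 * np.pi * (i + 0.5) / 4
        cx, cz = 6.0 * np.cos(az), 6.0 * np.sin(az)
        boxes.append(
            (
                f"bench_{i}",
                np.array([cx - 0.6, 0.0, cz - 0.4]),
                np.array([cx + 0.6, 0.9, cz + 0.4]),
            )
        )
    return SceneModel(boxes=boxes)


def raycast(origin, direction, scene: SceneModel):
    """Nearest forward intersection of gaze rays with the scene.

    Accepts single rays or ``(n, 3)`` batches.  Returns ``(points, ids)``
    where missed rays (sky) give NaN points and ``None`` ids.
    """
    o = np.atleast_2d(np.asarray(origin, dtype=float))
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    single = np.asarray(origin).ndim == 1
    n = o.shape[0]
    eps = 1e-9

    best_t = np.full(n, np.inf)
    best_id = np.full(n, None, dtype=object)

    # ground plane y = 0
    dy = d[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tg = -o[:, 1] / dy
    hit_g = (np.abs(dy) > eps) & (tg > eps)
    best_t = np.where(hit_g & (tg < best_t), tg, best_t)
    best_id[hit_g & (tg == best_t)] = scene.ground_id

    for bid, lo, hi in scene.boxes:
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / np.where(np.abs(d) > eps, d, np.where(d >= 0, eps, -eps))
        t1 = (lo[None, :] - o) * inv
        t2 = (hi[None, :] - o) * inv
        tmin = np.minimum(t1, t2).max(axis=1)
        tmax = np.maximum(t1, t2).min(axis=1)
        hit = (tmax >= tmin) & (tmax > eps)
        t_entry = np.where(tmin > eps, tmin, tmax)
        closer = hit & (t_entry < best_t)
        best_t = np.where(closer, t_entry, best_t)
        best_id[closer] = bid

    with np.errstate(invalid="ignore"):
        pts = o + best_t[:, None] * d
    miss = ~np.isfinite(best_t)
    pts[miss] = np.nan
    best_id[miss] = None
    if single:
        p = pts[0]
        return (None if np.any(np.isnan(p)) else p), best_id[0]
    return pts, best_id


@dataclass
class SimulationConfig:
    """All knobs of the simulator; every random draw is fixed by ``seed``."""

    duration: float = 60.0
    et_rate: float = 90.0
    timestamp_jitter_sd: float = 0.0009  # s; engine frame-time jitter
    # oculomotor statistics
    fixation_mean: float = 0.180         # s, gamma distributed
    fixation_shape: float = 4.0
    amplitude_median: float = 10.0       # deg, log-normal
    amplitude_sigma: float = 0.5
    main_seq_slope: float = 2.2          # ms per degree
    main_seq_intercept: float = 21.0     # ms
    elevation_range: tuple[float, float] = (-30.0, 12.0)  # deg
    horizontal_bias_sd: float = 25.0     # deg; tilt of saccade directions
    # head model
    eye_height: float = 1.6              # world units
    head_step_sd: float = 0.10           # units / sqrt(s) random walk
    head_follow: float = 0.6             # fraction of gaze the head adopts
    # corruption
    direction_noise_sd: float = 0.0      # deg per tangent axis
    blink_rate: float = 0.0              # per minute
    blink_mean: float = 0.150            # s, gamma(shape 4)
    frame_drop_prob: float = 0.0
    # EEG
    eeg_rate: float = 512.0
    eeg_start_t: float = 0.0             # first EEG timestamp on its own clock
    evoked_latency: float = 0.100        # s
    evoked_width: float = 0.015          # s (gaussian sd)
    evoked_amplitude: float = 1.0        # uV
    osc_freq: float = 10.0               # Hz
    osc_amplitude: float = 1.0           # uV
    osc_gain: float = 0.5                # amplitude factor post-onset
    osc_window: tuple[float, float] = (0.150, 0.400)  # s after onset
    noise_exponent: float = 1.0          # 1/f^exponent background
    noise_sd: float = 5.0                # uV
    clock_drift: float = 0.053           # s accumulated over the recording
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration",
            "et_rate",
            "fixation_mean",
            "fixation_shape",
            "amplitude_median",
            "eeg_rate",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """The simulator's true events, onsets on both clocks, and templates."""

    events: list[tuple[str, float, float, str | None]]  # kind, on, off, object
    gaze_onsets_et: np.ndarray
    gaze_onsets_eeg: np.ndarray
    clock: ClockModel
    template: np.ndarray | None = None
    template_times: np.ndarray | None = None
    config: SimulationConfig | None = None

    def to_event_sequence(self, rec: GazeRecording) -> EventSequence:
        """Reference labels on the recording's sample grid.

        Samples inside invalid (blink) stretches of ``rec`` are labelled
        invalid — the simulator knows it corrupted them — and everything else
        takes the kind of the true event covering its timestamp.
        """
        onsets = np.array([ev[1] for ev in self.events])
        kinds = [ev[0] for ev in self.events]
        idx = np.clip(np.searchsorted(onsets, rec.t, "right") - 1, 0, len(kinds) - 1)
        labels = np.array([kinds[i] for i in idx], dtype=object)
        labels[~rec.valid] = INVALID
        events: list[OculomotorEvent] = []
        i = 0
        n = len(labels)
        while i < n:
            j = i
            while j + 1 < n and labels[j + 1] == labels[i]:
                j += 1
            t_off = rec.t[j + 1] if j + 1 < n else rec.t[j] + 1.0 / rec.nominal_rate
            events.append(
                OculomotorEvent(
                    kind=str(labels[i]),
                    t_on=float(rec.t[i]),
                    t_off=float(t_off),
                    i_on=i,
                    i_off=j,
                )
            )
            i = j + 1
        return EventSequence(events=events, source="ground_truth")


def _spherical_dir(azimuth: float, elevation: float) -> np.ndarray:
    """Unit vector from azimuth (around y) and elevation (from horizontal)."""
    ca, sa = np.cos(azimuth), np.sin(azimuth)
    ce, se = np.cos(elevation), np.sin(elevation)
    return np.array([ce * sa, se, ce * ca])


def _to_spherical(d: np.ndarray) -> tuple[float, float]:
    return float(np.arctan2(d[0], d[2])), float(np.arcsin(np.clip(d[1], -1, 1)))


def _slerp(a: np.ndarray, b: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors, vectorised over s."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    theta = np.arccos(dot)
    if theta < 1e-9:
        return np.repeat(a[None, :], len(s), axis=0)
    sin_t = np.sin(theta)
    w1 = np.sin((1.0 - s) * theta) / sin_t
    w2 = np.sin(s * theta) / sin_t
    return w1[:, None] * a[None, :] + w2[:, None] * b[None, :]


def _head_path(cfg: SimulationConfig, t: np.ndarray, rng, walk_bounds) -> np.ndarray:
    """Bounded horizontal random walk at eye height (slow, walking-like)."""
    n = t.size
    pos = np.zeros((n, 3))
    pos[:, 1] = cfg.eye_height
    (x0, x1), (z0, z1) = walk_bounds
    xz = np.zeros(2)
    dts = np.diff(t, prepend=t[0] - 1.0 / cfg.et_rate)
    steps = rng.standard_normal((n, 2))
    for k in range(n):
        dt = max(dts[k], 0.0)
        xz = xz - 0.05 * xz * dt + cfg.head_step_sd * np.sqrt(dt) * steps[k]
        xz[0] = np.clip(xz[0], x0, x1)
        xz[1] = np.clip(xz[1], z0, z1)
        pos[k, 0], pos[k, 2] = xz
    return pos


def simulate_scanpath(
    config: SimulationConfig,
    scene: SceneModel | None = None,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate a clean 90-Hz gaze recording plus its ground truth.

    Fixations hold a world-fixed target point (so the translation-corrected
    velocity is exactly zero however the head moves); saccades rotate the
    gaze between targets along a raised-cosine velocity profile whose
    duration follows the configured main-sequence law.
    """
    cfg = config
    scene = scene if scene is not None else default_scene()
    rng = np.random.default_rng(cfg.seed)

    # jittered engine frame times
    period = 1.0 / cfg.et_rate
    n_approx = int(np.ceil(cfg.duration * cfg.et_rate)) + 2
    dts = period + cfg.timestamp_jitter_sd * rng.standard_normal(n_approx)
    dts = np.clip(dts, 0.3 * period, 2.0 * period)
    t = np.concatenate(([0.0], np.cumsum(dts)))
    t = t[t <= cfg.duration]
    n = t.size

    head_pos = _head_path(cfg, t, rng, scene.walk_bounds)

    # event schedule with per-fixation targets
    events: list[tuple[str, float, float, str | None]] = []
    targets: list[tuple[np.ndarray, str | None]] = []
    az0 = rng.uniform(-np.pi, np.pi)
    cur_dir = _spherical_dir(az0, np.radians(-10.0))
    clock = 0.0
    lo_el, hi_el = np.radians(cfg.elevation_range[0]), np.radians(cfg.elevation_range[1])

    def pick_target(origin: np.ndarray, direction: np.ndarray, amp_deg: float):
        az, el = _to_spherical(direction)
        for _ in range(12):
            tilt = np.radians(rng.normal(0.0, cfg.horizontal_bias_sd))
            sign = rng.choice([-1.0, 1.0])
            d_az = sign * np.radians(amp_deg) * np.cos(tilt)
            d_el = np.radians(amp_deg) * np.sin(tilt)
            new_el = np.clip(el + d_el, lo_el, hi_el)
            cand = _spherical_dir(az + d_az, new_el)
            pt, obj = raycast(origin, cand, scene)
            if pt is not None and np.linalg.norm(pt - origin) > 0.5:
                return cand, pt, obj
        cand = _spherical_dir(az + np.radians(amp_deg), np.radians(-12.0))
        pt, obj = raycast(origin, cand, scene)
        return cand, pt, obj

    # initial fixation target; targets[g] belongs to the g-th gaze event and
    # is appended before any saccade that needs it as its landing point
    cur_dir, pt, obj = pick_target(head_pos[0], cur_dir, 0.1)
    targets.append((pt, obj))
    while clock < cfg.duration:
        fdur = rng.gamma(cfg.fixation_shape, cfg.fixation_mean / cfg.fixation_shape)
        f_end = min(clock + fdur, cfg.duration)
        events.append((GAZE, clock, f_end, targets[-1][1]))
        clock = f_end
        if clock >= cfg.duration:
            break
        amp = cfg.amplitude_median * np.exp(cfg.amplitude_sigma * rng.standard_normal())
        sdur = (cfg.main_seq_slope * amp + cfg.main_seq_intercept) / 1000.0
        s_end = min(clock + sdur, cfg.duration)
        k_on = min(int(np.searchsorted(t, clock)), n - 1)
        cur_dir, pt, obj = pick_target(head_pos[k_on], cur_dir, amp)
        targets.append((pt, obj))
        events.append((SACCADE, clock, s_end, None))
        clock = s_end

    # render samples
    eye_dir = np.zeros((n, 3))
    hit_point = np.full((n, 3), np.nan)
    hit_object = np.full(n, None, dtype=object)
    onsets = np.array([ev[1] for ev in events])
    ev_idx = np.clip(np.searchsorted(onsets, t, "right") - 1, 0, len(events) - 1)

    fix_counter = -1
    for e, (kind, t_on, t_off, obj_e) in enumerate(events):
        mask = ev_idx == e
        if not mask.any():
            if kind == GAZE:
                fix_counter += 1
            continue
        ks = np.flatnonzero(mask)
        if kind == GAZE:
            fix_counter += 1
            tgt = targets[fix_counter][0]
            vec = tgt[None, :] - head_pos[ks]
            eye_dir[ks] = vec / np.linalg.norm(vec, axis=1, keepdims=True)
            hit_point[ks] = tgt
            hit_object[ks] = targets[fix_counter][1]
        else:
            p = (t[ks] - t_on) / max(t_off - t_on, 1e-9)
            s = p - np.sin(2 * np.pi * p) / (2 * np.pi)  # raised-cosine position
            prev_t = targets[fix_counter][0]
            next_t = targets[fix_counter + 1][0]
            for idx_local, k in enumerate(ks):
                d1 = prev_t - head_pos[k]
                d2 = next_t - head_pos[k]
                d1 /= np.linalg.norm(d1)
                d2 /= np.linalg.norm(d2)
                eye_dir[k] = _slerp(d1, d2, np.array([s[idx_local]]))[0]
                eye_dir[k] /= np.linalg.norm(eye_dir[k])
            pts, objs = raycast(head_pos[ks], eye_dir[ks], scene)
            hit_point[ks] = pts
            hit_object[ks] = objs

    # head direction lazily follows the gaze (horizontal preference emerges
    # because most targets sit near eye height)
    alpha = 0.05
    blended = cfg.head_follow * eye_dir + (1.0 - cfg.head_follow) * np.array(
        [0.0, 0.0, 1.0]
    )
    head_dir = lfilter([alpha], [1.0, -(1.0 - alpha)], blended, axis=0)
    head_dir[0] = blended[0]
    head_dir /= np.linalg.norm(head_dir, axis=1, keepdims=True)

    rec = GazeRecording(
        t=t,
        eye_origin=head_pos,
        eye_dir=eye_dir,
        head_pos=head_pos,
        head_dir=head_dir,
        hit_point=hit_point,
        hit_object=hit_object,
        valid=np.ones(n, dtype=bool),
        provenance=np.zeros(n, dtype=np.int8),
        nominal_rate=cfg.et_rate,
        meta={"source": "synthetic", "seed": cfg.seed},
    )

    clock_model = ClockModel(
        offset=cfg.eeg_start_t,
        drift_total=cfg.clock_drift,
        t0_et=float(t[0]),
        t1_et=float(t[-1]),
        method="endpoint",
    )
    gaze_onsets = np.array(
        [ev[1] for i, ev in enumerate(events) if ev[0] == GAZE and i > 0]
    )
    truth = GroundTruth(
        events=events,
        gaze_onsets_et=gaze_onsets,
        gaze_onsets_eeg=to_eeg_time(gaze_onsets, clock_model),
        clock=clock_model,
        config=cfg,
    )
    return rec, truth


def corrupt(rec: GazeRecording, config: SimulationConfig, scene: SceneModel | None = None) -> GazeRecording:
    """Apply the sensor/noise model: direction noise, blinks, frame drops."""
    cfg = config
    scene = scene if scene is not None else default_scene()
    rng = np.random.default_rng(cfg.seed + 1)
    out = rec.copy()
    n = len(out)

    if cfg.direction_noise_sd > 0:
        sd = np.radians(cfg.direction_noise_sd)
        d = out.eye_dir
        ref = np.where(
            np.abs(d[:, 1:2]) < 0.9, [[0.0, 1.0, 0.0]], [[1.0, 0.0, 0.0]]
        )
        u = np.cross(ref, d)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(d, u)
        noise = rng.standard_normal((n, 2)) * sd
        d = d + noise[:, :1] * u + noise[:, 1:] * v
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        out.eye_dir = d
        pts, objs = raycast(out.eye_origin, d, scene)
        out.hit_point = pts
        out.hit_object = objs

    if cfg.blink_rate > 0:
        n_blinks = rng.poisson(cfg.blink_rate * out.duration / 60.0)
        starts = np.sort(rng.uniform(out.t[0], out.t[-1], n_blinks))
        durs = rng.gamma(4.0, cfg.blink_mean / 4.0, n_blinks)
        for s, d_ in zip(starts, durs):
            mask = (out.t >= s) & (out.t <= s + d_)
            out.valid[mask] = False
            out.hit_point[mask] = np.nan
            out.hit_object[mask] = None
            out.eye_dir[mask] = 0.0

    if cfg.frame_drop_prob > 0:
        keep = rng.random(n) >= cfg.frame_drop_prob
        keep[0] = keep[-1] = True
        out = GazeRecording(
            t=out.t[keep],
            eye_origin=out.eye_origin[keep],
            eye_dir=out.eye_dir[keep],
            head_pos=out.head_pos[keep],
            head_dir=out.head_dir[keep],
            hit_point=out.hit_point[keep],
            hit_object=out.hit_object[keep],
            valid=out.valid[keep],
            provenance=out.provenance[keep],
            nominal_rate=out.nominal_rate,
            meta=dict(out.meta),
        )
    return out


def simulate_eeg(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
) -> tuple[EEGRecording, ClockModel]:
    """Render gaze-onset-locked EEG on the (drifting) EEG clock.

    The EEG stream covers exactly the co-recorded interval: its duration
    equals the eye-tracking duration plus the configured clock drift, which
    is what the endpoint drift estimator exploits.  Channel 0 carries the
    evoked template at every true gaze onset plus an ongoing oscillation
    whose amplitude is multiplied by ``osc_gain`` inside the post-onset
    window, on top of 1/f^exponent noise.
    """
    cfg = config if config is not None else truth.config
    if cfg is None:
        raise ConfigError("no simulation config available")
    rng = np.random.default_rng(cfg.seed + 2)
    clock = truth.clock
    rate = cfg.eeg_rate
    eeg_span = (clock.t1_et - clock.t0_et) + clock.drift_total
    n = int(np.rint(eeg_span * rate)) + 1

    # 1/f^x background
    if cfg.noise_sd > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / rate)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-cfg.noise_exponent / 2.0)
        x = np.fft.irfft(spec * shape, n)
        x *= cfg.noise_sd / max(x.std(), 1e-12)
    else:
        x = np.zeros(n)

    # evoked template, stored for recovery checks
    tt = np.arange(0.0, cfg.evoked_latency + 5 * cfg.evoked_width, 1.0 / rate)
    template = cfg.evoked_amplitude * np.exp(
        -0.5 * ((tt - cfg.evoked_latency) / cfg.evoked_width) ** 2
    )
    truth.template = template
    truth.template_times = tt

    onset_idx = np.rint(truth.gaze_onsets_eeg * rate).astype(int)
    for i in onset_idx:
        j1 = min(i + template.size, n)
        if i < 0 or i >= n:
            continue
        x[i:j1] += template[: j1 - i]

    # induced oscillation with post-onset amplitude change
    if cfg.osc_amplitude > 0:
        env = np.ones(n)
        w0 = int(np.rint(cfg.osc_window[0] * rate))
        w1 = int(np.rint(cfg.osc_window[1] * rate))
        for i in onset_idx:
            a, b = max(i + w0, 0), min(i + w1, n)
            if a < b:
                env[a:b] = cfg.osc_gain
        phase = rng.uniform(0, 2 * np.pi)
        tgrid = np.arange(n) / rate
        x += cfg.osc_amplitude * env * np.sin(2 * np.pi * cfg.osc_freq * tgrid + phase)

    eeg = EEGRecording(
        data=x[None, :], rate=rate, start_t=cfg.eeg_start_t, channels=["Oz"]
    )
    return eeg, clock
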