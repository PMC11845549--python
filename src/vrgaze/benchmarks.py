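"""End-to-end validation experiments against the simulator's ground truth.

Each function runs one self-contained experiment — geometry invariances,
classification recovery, clock-drift recovery, fERP/fERSP recovery, the
shift-correlation pattern, determinism — and returns plain numbers.  The
acceptance script and the acceptance tests both call these, so the reported
figures are always recomputed from scratch.
"""

from __future__ import annotations

import io as _io

import numpy as np

from .fixation_eeg import EpochSet, morlet_tf
from .io import GazeSample, write_events
from .kinematics import angular_velocity_step
from .model import FixationModel, GazeClassifier
from .segment_classify import data_driven_boundaries, fixed_boundaries
from .sync import estimate_clock_drift, to_eeg_time
from .synthetic import SimulationConfig, corrupt, simulate_eeg, simulate_scanpath
from .validate import compare_labels

__all__ = [
    "translation_invariance",
    "geometry_oracle",
    "classification_recovery",
    "segmentation_counts",
    "drift_recovery",
    "erp_recovery",
    "morlet_peak_check",
    "db_stationarity",
    "shift_correlation_pattern",
    "determinism_check",
]


def _sample(t, origin, hit, eye_dir=None):
    origin = np.asarray(origin, dtype=float)
    hit = np.asarray(hit, dtype=float)
    if eye_dir is None:
        eye_dir = (hit - origin) / np.linalg.norm(hit - origin)
    return GazeSample(
        t=t, eye_origin=origin, eye_dir=eye_dir, head_pos=origin, head_dir=eye_dir,
        hit_point=hit,
    )


def translation_invariance(n_paths: int = 1000, seed: int = 0) -> float:
    """Max |w| (deg/s) over random observer paths with a fixed hit point.

    Exact translation invariance demands zero for every path.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_paths):
        hit = rng.uniform(-20, 20, 3)
        hit[1] = abs(hit[1]) + 0.5
        p1 = rng.uniform(-3, 3, 3)
        p2 = p1 + rng.normal(0, 0.05, 3)
        if min(np.linalg.norm(hit - p1), np.linalg.norm(hit - p2)) < 0.5:
            continue
        s1 = _sample(0.0, p1, hit.copy())
        s2 = _sample(1 / 90, p2, hit.copy())
        worst = max(worst, abs(angular_velocity_step(s1, s2)))
    return worst


def geometry_oracle(n_cases: int = 10000, seed: int = 0) -> float:
    """Max relative error vs the direct inter-vector angle (static observer).

    For displacements up to 10 degrees at matched distances the corrected
    velocity must agree with arccos of the dot product of the two directions.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        d1 = rng.normal(size=3)
        d1 /= np.linalg.norm(d1)
        ang = np.radians(rng.uniform(0.1, 10.0))
        ax = np.cross(d1, rng.normal(size=3))
        ax /= np.linalg.norm(ax)
        d2 = d1 * np.cos(ang) + np.cross(ax, d1) * np.sin(ang)
        dist = rng.uniform(1.0, 30.0)
        w = angular_velocity_step(
            _sample(0.0, np.zeros(3), d1 * dist), _sample(1.0, np.zeros(3), d2 * dist)
        )
        direct = np.degrees(ang)
        worst = max(worst, abs(w - direct) / direct)
    return worst


def classification_recovery(
    duration: float = 600.0,
    seed: int = 0,
    noisy: bool = False,
) -> dict[str, float]:
    """Full-loop recovery: simulate (-> corrupt) -> classify -> score.

    Agreement is sample-by-sample over {gaze, saccade, invalid} against the
    simulator's truth (blink-corrupted samples count as invalid in the
    reference); onset error is the distance from each detected gaze onset to
    the nearest true one, in eye-tracking samples.
    """
    cfg = SimulationConfig(
        duration=duration,
        seed=seed,
        direction_noise_sd=0.5 if noisy else 0.0,
        blink_rate=3.0 if noisy else 0.0,
        frame_drop_prob=0.005 if noisy else 0.0,
    )
    rec, truth = simulate_scanpath(cfg)
    rec = corrupt(rec, cfg)
    result = GazeClassifier(rec).fit(reject_outliers=False)
    ref = truth.to_event_sequence(result.recording)
    mat = compare_labels(result.events, ref, result.recording)
    m = mat.to_numpy()
    agreement = float(np.trace(m) / m.sum())

    pred = result.gaze_onsets(eeg_usable_only=False)
    true_on = truth.gaze_onsets_et
    errors = np.array([np.min(np.abs(true_on - p)) for p in pred])
    return {
        "agreement": agreement,
        "median_onset_error_samples": float(
            np.median(errors) * cfg.et_rate
        ),
        "n_detected_gazes": int(pred.size),
        "n_true_gazes": int(true_on.size),
    }


def segmentation_counts(seed: int = 0, duration: float = 60.0) -> dict[str, float]:
    """Boundary counts of both segmentation methods on one noisy recording."""
    cfg = SimulationConfig(duration=duration, seed=seed, direction_noise_sd=0.3)
    rec, _ = simulate_scanpath(cfg)
    rec = corrupt(rec, cfg)
    model = GazeClassifier(rec)
    fitted = model.fit()
    vs = fitted.velocity
    dd = data_driven_boundaries(vs)
    fx = fixed_boundaries(fitted.recording)
    return {
        "data_driven_boundaries": len(dd),
        "data_driven_expected": int(round(2.0 * vs.duration)),
        "fixed_boundaries": len(fx),
        "fixed_expected": int(fitted.recording.duration // 10),
    }


def drift_recovery(duration: float = 1800.0, seed: int = 0) -> dict[str, float]:
    """Recover an injected 53-ms linear drift over a long recording.

    Residual misalignment of true gaze onsets after correction must stay
    below half an EEG sample period.
    """
    cfg = SimulationConfig(
        duration=duration, seed=seed, clock_drift=0.053, frame_drop_prob=0.002
    )
    rec, truth = simulate_scanpath(cfg)
    rec = corrupt(rec, cfg)
    eeg, _ = simulate_eeg(truth, cfg)
    eeg_times = eeg.start_t + np.arange(eeg.n_times) / eeg.rate
    model = estimate_clock_drift(rec.t, eeg_times)
    resid = to_eeg_time(truth.gaze_onsets_et, model) - truth.gaze_onsets_eeg
    return {
        "injected_drift_ms": 53.0,
        "estimated_drift_ms": float(1000 * model.drift_total),
        "max_residual_ms": float(1000 * np.max(np.abs(resid))),
        "half_eeg_sample_ms": float(500.0 / eeg.rate),
    }


def _evoked_amplitude_for_snr(cfg: SimulationConfig, snr: float, window=0.7) -> float:
    """Template amplitude giving RMS(template)/RMS(noise) = snr over the window."""
    rate = cfg.eeg_rate
    tt = np.arange(0.0, cfg.evoked_latency + 5 * cfg.evoked_width, 1.0 / rate)
    unit = np.exp(-0.5 * ((tt - cfg.evoked_latency) / cfg.evoked_width) ** 2)
    rms_unit = np.sqrt((unit**2).sum() / (window * rate))
    return snr * cfg.noise_sd / rms_unit


def erp_recovery(seed: int = 0, n_trials: int = 500, snr: float = 0.2) -> dict[str, float]:
    """fERP recovery at a given SNR: correlation of the average with truth.

    Fixations are long enough that epochs do not overlap, so the average is
    an unbiased estimate of the injected template.
    """
    cfg = SimulationConfig(
        duration=1.12 * n_trials,
        seed=seed,
        fixation_mean=1.0,
        fixation_shape=8.0,
        noise_sd=5.0,
        osc_gain=1.0,  # stationary oscillation: part of the noise here
    )
    cfg.evoked_amplitude = _evoked_amplitude_for_snr(cfg, snr)
    rec, truth = simulate_scanpath(cfg)
    eeg, clock = simulate_eeg(truth, cfg)
    res = FixationModel(eeg, truth.gaze_onsets_et, clock, channel=0).fit(ersp=False)
    template = np.interp(
        res.erp_times, truth.template_times, truth.template, left=0.0, right=0.0
    )
    return {
        "template_correlation": float(np.corrcoef(res.erp, template)[0, 1]),
        "n_trials": res.n_trials,
        "snr": snr,
    }


def morlet_peak_check(freq: float = 10.0, rate: float = 512.0) -> float:
    """Frequency (Hz) at which the power of a pure sinusoid peaks."""
    n = int(2.05 * rate)
    t = np.arange(n) / rate - 0.875
    data = np.sin(2 * np.pi * freq * t)[None, None, :]
    ep = EpochSet(data=data, times=t, rate=rate, onsets=np.zeros(1))
    tf = morlet_tf(ep, crop=(-0.5, 0.8)).average()
    return float(tf.freqs[int(np.argmax(tf.power.mean(axis=1)))])


def db_stationarity(seed: int = 0, n_trials: int = 150) -> float:
    """Mean dB of the baselined ERSP of a stationary process (expected 0)."""
    cfg = SimulationConfig(
        duration=1.12 * n_trials,
        seed=seed,
        fixation_mean=1.0,
        fixation_shape=8.0,
        evoked_amplitude=0.0,
        osc_gain=1.0,  # no onset-locked change: fully stationary signal
        noise_sd=3.0,
    )
    rec, truth = simulate_scanpath(cfg)
    eeg, clock = simulate_eeg(truth, cfg)
    res = FixationModel(eeg, truth.gaze_onsets_et, clock, channel=0).fit(ersp=True)
    return float(res.ersp_db.power.mean())


def shift_correlation_pattern(seed: int = 0, duration: float = 120.0) -> dict:
    """Median trial-vs-average r per shift for ERP and ERSP modes.

    On evoked simulated data the ERP correlation must peak strictly at zero
    shift while the ERSP medians barely move — the time-sensitivity contrast
    between the two measures.
    """
    cfg = SimulationConfig(duration=duration, seed=seed)
    rec, truth = simulate_scanpath(cfg)
    eeg, clock = simulate_eeg(truth, cfg)
    model = FixationModel(eeg, truth.gaze_onsets_et, clock, channel=0)
    out: dict[str, dict[int, float]] = {}
    for mode in ("erp", "ersp"):
        rs = model.shift_correlation(mode=mode)
        out[mode] = {s: float(np.median(r)) for s, r in rs.items()}
    out["erp_spread"] = max(out["erp"].values()) - min(out["erp"].values())
    out["ersp_spread"] = max(out["ersp"].values()) - min(out["ersp"].values())
    return out


def determinism_check(seed: int = 0, duration: float = 30.0) -> bool:
    """Same seed/config twice -> byte-identical serialized event tables."""
    tables = []
    for _ in range(2):
        cfg = SimulationConfig(
            duration=duration, seed=seed, direction_noise_sd=0.3, blink_rate=3.0
        )
        rec, _ = simulate_scanpath(cfg)
        rec = corrupt(rec, cfg)
        res = GazeClassifier(rec).fit()
        buf = _io.StringIO()
        write_events(res.events, buf)
        tables.append(buf.getvalue())
    return tables[0] == tables[1]
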