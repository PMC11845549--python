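"""Plots for classification results and fixation-locked EEG."""

from __future__ import annotations

import numpy as np

from .segment_classify import SACCADE

_KIND_COLORS = {
    "gaze": "tab:blue",
    "saccade": "tab:red",
    "invalid": "0.6",
    "outlier_gaze": "tab:cyan",
    "outlier_saccade": "tab:orange",
}


def plot_classification(result, ax=None, tmin=None, tmax=None):
    """Velocity trace with per-event shading and the thresholds used."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    vs = result.velocity
    mask = np.ones(len(vs), dtype=bool)
    if tmin is not None:
        mask &= vs.t >= tmin
    if tmax is not None:
        mask &= vs.t <= tmax
    ax.plot(vs.t[mask], vs.w[mask], color="green", lw=0.8, label="eye velocity")
    for ev in result.events:
        if tmax is not None and ev.t_on > tmax:
            break
        if tmin is not None and ev.t_off < tmin:
            continue
        ax.axvspan(
            ev.t_on, ev.t_off, color=_KIND_COLORS.get(ev.kind, "0.8"), alpha=0.2
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("angular velocity (deg/s)")
    ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_erp(result, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.erp_times * 1000, result.erp, color="black")
    ax.axvline(0, color="red", lw=0.8)
    ax.set_xlabel("time from gaze onset (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"fERP ({result.n_trials} trials)")
    return ax


def plot_ersp(result, ax=None):
    import matplotlib.pyplot as plt

    if result.ersp_db is None:
        raise ValueError("result carries no ERSP; fit with ersp=True")
    if ax is None:
        _, ax = plt.subplots()
    tf = result.ersp_db
    vmax = float(np.nanmax(np.abs(tf.power)))
    mesh = ax.pcolormesh(
        tf.times * 1000, tf.freqs, tf.power, cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.axvline(0, color="black", ls="--", lw=0.8)
    ax.set_xlabel("time from gaze onset (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(mesh, ax=ax, label="power (dB)")
    return ax


def plot_main_sequence(seq, ax=None):
    """Saccade amplitude vs peak velocity scatter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pairs = [
        (ev.amplitude, ev.peak_vel)
        for ev in seq.of_kind(SACCADE)
        if np.isfinite(ev.amplitude) and np.isfinite(ev.peak_vel)
    ]
    if pairs:
        amp, vel = np.array(pairs).T
        ax.scatter(amp, vel, s=4, alpha=0.4)
    ax.set_xlabel("saccade amplitude (deg)")
    ax.set_ylabel("peak velocity (deg/s)")
    return ax
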