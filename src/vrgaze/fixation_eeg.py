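"""Gaze-onset-locked EEG analysis: fERPs, fERSPs, and shift correlations.

Without experimenter-controlled stimuli, gaze onsets (saccade offsets) play
the role of trial onsets.  This module epochs a clean channels x time EEG
matrix around gaze onsets mapped through the clock model, averages epochs
into a fixation-onset ERP (no baseline correction — there is no neutral
baseline in a continuous stream of gazes and saccades), computes a Morlet
time-frequency representation (3 cycles at every frequency, favouring time
resolution) with a dB baseline over -500..-200 ms, and quantifies time
sensitivity by correlating single trials, extracted at onsets shifted by
±1 eye-tracking sample (±11 ms at 90 Hz), with the un-shifted average.

Upstream EEG cleaning (filtering to 0.5 Hz, downsampling, ICA) is assumed
done; only a numeric matrix is required here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin

from .errors import ConfigError, DataError
from .io import EEGRecording
from .sync import ClockModel, map_onsets_to_eeg, to_eeg_time

__all__ = [
    "EpochSet",
    "TimeFrequencyMap",
    "extract_epochs",
    "average_erp",
    "highpass",
    "morlet_tf",
    "db_baseline",
    "shift_correlation",
]


@dataclass
class EpochSet:
    """Gaze-onset-locked EEG trials (trials x channels x time, microvolts)."""

    data: np.ndarray
    times: np.ndarray
    rate: float
    onsets: np.ndarray      # EEG sample index of t=0 for each kept trial
    dropped: int = 0
    channels: list | None = None

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])


@dataclass
class TimeFrequencyMap:
    """Morlet power (trials x freqs x time, or freqs x time when averaged)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    cycles: float = 3.0
    units: str = "uV^2"

    def average(self) -> "TimeFrequencyMap":
        if self.power.ndim == 2:
            return self
        return TimeFrequencyMap(
            power=self.power.mean(axis=0),
            freqs=self.freqs,
            times=self.times,
            cycles=self.cycles,
            units=self.units,
        )

    def crop(self, tmin: float, tmax: float) -> "TimeFrequencyMap":
        keep = (self.times >= tmin) & (self.times <= tmax)
        return TimeFrequencyMap(
            power=self.power[..., keep],
            freqs=self.freqs,
            times=self.times[keep],
            cycles=self.cycles,
            units=self.units,
        )


def extract_epochs(
    eeg: EEGRecording,
    onset_indices: np.ndarray,
    window: tuple[float, float] = (-0.200, 0.500),
) -> EpochSet:
    """Cut half-open index windows around EEG-sample onsets.

    For onset index ``i`` the window ``[i + round(w0*rate), i + round(w1*rate))``
    is extracted; onsets whose window leaves the matrix are dropped and
    counted, so ``n_trials + dropped == len(onset_indices)``.
    """
    onset_indices = np.asarray(onset_indices, dtype=np.int64)
    w0 = int(round(window[0] * eeg.rate))
    w1 = int(round(window[1] * eeg.rate))
    length = w1 - w0
    if length <= 0:
        raise ConfigError("window must have positive length")
    starts = onset_indices + w0
    ok = (starts >= 0) & (starts + length <= eeg.n_times)
    kept = onset_indices[ok]
    data = np.empty((kept.size, eeg.data.shape[0], length))
    for k, i in enumerate(kept):
        data[k] = eeg.data[:, i + w0 : i + w1]
    times = (np.arange(w0, w1)) / eeg.rate
    return EpochSet(
        data=data,
        times=times,
        rate=eeg.rate,
        onsets=kept,
        dropped=int((~ok).sum()),
        channels=list(eeg.channels),
    )


def average_erp(epochs: EpochSet) -> np.ndarray:
    """Arithmetic mean across trials (channels x time); no baseline applied."""
    if epochs.n_trials == 0:
        raise DataError("cannot average zero trials")
    return epochs.data.mean(axis=0)


def highpass(eeg: EEGRecording, cutoff: float) -> EEGRecording:
    """Zero-phase windowed-sinc (Hamming) FIR high-pass.

    The transition band is 25% of the cutoff (at least 1 Hz); the symmetric
    kernel applied with a centred convolution is exactly zero-phase.
    """
    nyq = eeg.rate / 2.0
    if cutoff >= nyq:
        raise ConfigError("cutoff must be below the Nyquist frequency")
    trans = max(0.25 * cutoff, 1.0)
    numtaps = int(np.ceil(3.3 * eeg.rate / trans))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay of 0
    taps = firwin(numtaps, cutoff, window="hamming", pass_zero=False, fs=eeg.rate)
    # pad with edge values so the transient stays outside the data span
    half = numtaps // 2
    padded = np.pad(eeg.data, ((0, 0), (half, half)), mode="edge")
    out = fftconvolve(padded, taps[None, :], mode="same", axes=1)[:, half:-half]
    return EEGRecording(
        data=out, rate=eeg.rate, start_t=eeg.start_t, channels=list(eeg.channels)
    )


def morlet_wavelet(
    freq: float, rate: float, cycles: float = 3.0, gwidth: float = 3.0
) -> np.ndarray:
    """Zero-mean complex Morlet wavelet, Gaussian truncated at ±gwidth sigma.

    ``sigma_t = cycles / (2 pi f)``.  Amplitude (L1) normalised: a unit
    complex exponential at the wavelet's frequency yields unit power, so a
    sinusoid's power peaks exactly at its own frequency bin.  (White noise
    consequently has expected power proportional to f, the wavelet
    bandwidth; dB baselining is per-frequency and unaffected.)
    """
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = np.arange(0.0, gwidth * sigma_t, 1.0 / rate)
    t = np.concatenate([-half[:0:-1], half])
    w = np.exp(2j * np.pi * freq * t - t**2 / (2.0 * sigma_t**2))
    w -= w.mean()  # remove the (tiny) DC leakage of the truncated Gaussian
    return w / np.abs(w).sum()


def morlet_tf(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    cycles: float = 3.0,
    channel: int | str = 0,
    crop: tuple[float, float] | None = (-0.500, 0.800),
    gwidth: float = 3.0,
) -> TimeFrequencyMap:
    """Per-trial Morlet wavelet power for one channel.

    Default frequency grid 2..45 Hz in 0.5-Hz steps with a fixed 3 cycles at
    every frequency (time resolution over frequency resolution).  The epoch
    must be at least one wavelet long at the lowest frequency; edges closer
    to the epoch border than half a wavelet are contaminated and should be
    removed via ``crop``.
    """
    if freqs is None:
        freqs = np.arange(2.0, 45.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ConfigError("freqs must be strictly increasing")
    if isinstance(channel, str):
        channel = epochs.channels.index(channel)
    data = epochs.data[:, channel, :]
    n_times = data.shape[1]
    power = np.empty((epochs.n_trials, freqs.size, n_times))
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, epochs.rate, cycles, gwidth)
        if w.size > n_times:
            raise DataError(
                f"epoch shorter than one {cycles}-cycle wavelet at {f} Hz"
            )
        conv = fftconvolve(data, w[None, :], mode="same", axes=1)
        power[:, fi, :] = np.abs(conv) ** 2
    tf = TimeFrequencyMap(power=power, freqs=freqs, times=epochs.times, cycles=cycles)
    if crop is not None:
        tf = tf.crop(*crop)
    return tf


def db_baseline(
    tf_avg: TimeFrequencyMap,
    baseline: tuple[float, float] = (-0.500, -0.200),
) -> TimeFrequencyMap:
    """Decibel-normalise trial-averaged power against a pre-onset baseline.

    ``P_db(f, t) = 10 log10(P(f, t) / mean_t' in baseline P(f, t'))``.  The
    baseline window precedes the saccade leading into the gaze so that
    saccadic power does not bias the reference.
    """
    tf = tf_avg.average()
    keep = (tf.times >= baseline[0]) & (tf.times <= baseline[1])
    if not keep.any():
        raise ConfigError("baseline window lies outside the epoch")
    base = tf.power[:, keep].mean(axis=1)
    if np.any(base <= 0):
        raise DataError("zero baseline power")
    return TimeFrequencyMap(
        power=10.0 * np.log10(tf.power / base[:, None]),
        freqs=tf.freqs,
        times=tf.times,
        cycles=tf.cycles,
        units="dB",
    )


def _pearson_rows(rows: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson r of each row against a template, vectorised."""
    x = rows - rows.mean(axis=1, keepdims=True)
    y = template - template.mean()
    denom = np.sqrt((x**2).sum(axis=1) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x @ y) / denom


def shift_correlation(
    eeg: EEGRecording,
    onsets_et: np.ndarray,
    model: ClockModel,
    et_rate: float = 90.0,
    mode: str = "erp",
    shifts: tuple[int, ...] = (-1, 0, 1),
    channel: int | str = 0,
    window: tuple[float, float] = (-0.200, 0.500),
    tf_window: tuple[float, float] = (-0.875, 1.175),
    freqs: np.ndarray | None = None,
    cycles: float = 3.0,
    hp_cutoff: float | None = 5.0,
) -> dict[int, np.ndarray]:
    """Correlate single trials at shifted onsets with the un-shifted average.

    For every shift ``s`` (in eye-tracking samples, i.e. ``s/et_rate``
    seconds), trials are re-extracted at the shifted onsets and each is
    correlated (Pearson) with the average computed at shift 0 — the ERP time
    course for ``mode="erp"``, or the trial-averaged Morlet power plane over
    ``window``, flattened across frequencies and times, for ``mode="ersp"``.
    The data are high-pass filtered first (default 5 Hz) since slow drifts
    are not the target of this comparison.  Returns ``{shift: r_values}``.
    """
    if mode not in ("erp", "ersp"):
        raise ConfigError(f"unknown mode {mode!r}")
    if hp_cutoff is not None:
        eeg = highpass(eeg, hp_cutoff)
    if isinstance(channel, str):
        channel = eeg.channels.index(channel)

    onsets_et = np.asarray(onsets_et, dtype=float)
    ep_window = window if mode == "erp" else tf_window

    def trials_at(shift: int):
        idx, ok = map_onsets_to_eeg(
            onsets_et + shift / et_rate, model, eeg.rate, eeg.n_times
        )
        return extract_epochs(eeg, idx[ok], ep_window)

    base = trials_at(0)
    if base.n_trials < 2:
        raise DataError("need at least 2 trials")

    if mode == "erp":
        template = average_erp(base)[channel]
    else:
        tf0 = morlet_tf(base, freqs=freqs, cycles=cycles, channel=channel, crop=window)
        template = tf0.average().power.ravel()

    out: dict[int, np.ndarray] = {}
    for s in shifts:
        ep = base if s == 0 else trials_at(s)
        if mode == "erp":
            rows = ep.data[:, channel, :]
        else:
            tfs = tf0 if s == 0 else morlet_tf(
                ep, freqs=freqs, cycles=cycles, channel=channel, crop=window
            )
            rows = tfs.power.reshape(tfs.power.shape[0], -1)
        out[s] = _pearson_rows(rows, template)
    return out


def gaze_onsets_to_eeg_indices(
    seq,
    model: ClockModel,
    eeg: EEGRecording,
) -> np.ndarray:
    """Convenience: EEG sample indices of a sequence's usable gaze onsets."""
    onsets = seq.gaze_onsets(eeg_usable_only=True)
    idx, ok = map_onsets_to_eeg(onsets, model, eeg.rate, eeg.n_times)
    return idx[ok]
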