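"""High-level modelling interface: classifier and fixation-EEG models.

`GazeClassifier` bundles the full eye-movement pipeline — preprocessing,
translation-corrected velocity, adaptive segmentation/thresholding, event
repair — behind a fit() that returns a `GazeClassificationResult` carrying
the event sequence, the thresholds actually used, and summary diagnostics.
`FixationModel` does the same for the EEG side: epoching at gaze onsets
mapped through a clock model, fERP averaging, Morlet fERSP with dB baseline,
and the trial-vs-average shift-correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixation_eeg as feeg
from . import kinematics, preprocess, segment_classify as sc, validate
from .io import EEGRecording, GazeRecording, read_gaze_table, renormalize_directions
from .sync import ClockModel, map_onsets_to_eeg, regularize_et_timestamps

__all__ = ["GazeClassifier", "GazeClassificationResult", "FixationModel", "FixationResult"]


class GazeClassifier:
    """Velocity-based gaze/saccade classifier for 3D VR eye tracking.

    Parameters
    ----------
    recording : raw gaze recording (any validity flags already set).
    segmentation : ``"data_driven"`` (default) or ``"fixed_10s"``.
    k : MAD multiplier of the adaptive velocity threshold.
    target_rate : boundary frequency (Hz) for the data-driven segmentation.
    clip : velocity ceiling in deg/s.
    sg_window, sg_order : Savitzky-Golay smoothing of the velocity series.
    min_saccade, min_gaze : shortest biologically plausible durations (s).
    outlier_multiplier : pooled MAD multiplier flagging too-long events.
    expand_pad, min_invalid, max_gap : validity-handling parameters (s).
    """

    def __init__(
        self,
        recording: GazeRecording,
        *,
        segmentation: str = "data_driven",
        k: float = 3.0,
        target_rate: float = 2.0,
        fixed_interval: float = 10.0,
        clip: float = 1000.0,
        sg_window: int = 5,
        sg_order: int = 2,
        min_saccade: float = 0.020,
        min_gaze: float = 0.040,
        outlier_multiplier: float = 3.5,
        expand_pad: float = 0.023,
        min_invalid: float = 0.020,
        max_gap: float = 0.250,
        median_filter: bool = True,
    ) -> None:
        if segmentation not in ("data_driven", "fixed_10s"):
            raise ValueError(f"unknown segmentation {segmentation!r}")
        self.recording = recording
        self.segmentation = segmentation
        self.k = k
        self.target_rate = target_rate
        self.fixed_interval = fixed_interval
        self.clip = clip
        self.sg_window = sg_window
        self.sg_order = sg_order
        self.min_saccade = min_saccade
        self.min_gaze = min_gaze
        self.outlier_multiplier = outlier_multiplier
        self.expand_pad = expand_pad
        self.min_invalid = min_invalid
        self.max_gap = max_gap
        self.median_filter = median_filter

    @classmethod
    def from_table(cls, path, column_map=None, *, delimiter="\t", nominal_rate=90.0, **kwargs):
        rec = read_gaze_table(
            path, column_map, delimiter=delimiter, nominal_rate=nominal_rate
        )
        return cls(rec, **kwargs)

    def fit(self, *, reject_outliers: bool = True) -> "GazeClassificationResult":
        """Run the full pipeline and return the classified result."""
        rec = renormalize_directions(self.recording)
        rec = regularize_et_timestamps(rec)
        rec = preprocess.preprocess_recording(
            rec,
            min_invalid=self.min_invalid,
            pad=self.expand_pad,
            max_gap=self.max_gap,
            median_filter=self.median_filter,
        )
        vs = kinematics.angular_velocity(rec)
        vs = kinematics.condition_velocity(
            vs, clip=self.clip, sg_window=self.sg_window, sg_order=self.sg_order
        )
        if self.segmentation == "data_driven":
            segments = sc.data_driven_boundaries(
                vs, k=self.k, target_rate=self.target_rate
            )
        else:
            segments = sc.fixed_boundaries(rec, interval=self.fixed_interval)
        labels, thresholds = sc.classify_samples(vs, segments, k=self.k)
        seq = sc.build_events(labels, rec, vs)
        seq = sc.merge_short_events(
            seq, min_saccade=self.min_saccade, min_gaze=self.min_gaze
        )
        seq = sc.attach_gaze_centroids(seq, rec)
        seq = sc.attach_saccade_amplitudes(seq, rec)
        if reject_outliers:
            seq = sc.reject_long_outliers(seq, multiplier=self.outlier_multiplier)
        seq = sc.assign_gaze_object(seq, rec)
        seq = sc.reject_invalid_overlap(seq, rec)
        return GazeClassificationResult(
            model=self,
            recording=rec,
            velocity=vs,
            segments=segments,
            thresholds=thresholds,
            events=seq,
        )


@dataclass
class GazeClassificationResult:
    """Classified events plus the intermediates needed to audit them."""

    model: GazeClassifier
    recording: GazeRecording
    velocity: kinematics.VelocitySeries
    segments: sc.SegmentSet
    thresholds: np.ndarray
    events: sc.EventSequence

    def duration_stats(self):
        return validate.duration_summary(self.events)

    def main_sequence(self):
        return validate.main_sequence(self.events)

    def gaze_onsets(self, *, eeg_usable_only: bool = True) -> np.ndarray:
        return self.events.gaze_onsets(eeg_usable_only=eeg_usable_only)

    def time_shares(self) -> dict[str, float]:
        """Fraction of classified time per event category."""
        total = sum(ev.duration for ev in self.events)
        shares: dict[str, float] = {}
        for ev in self.events:
            shares[ev.kind] = shares.get(ev.kind, 0.0) + ev.duration
        return {k: v / total for k, v in shares.items()} if total else shares

    def validation_report(self, ref_seq=None) -> validate.ValidationReport:
        return validate.ValidationReport.from_classification(
            self.events, self.recording, ref_seq
        )

    def summary(self) -> str:
        """Human-readable classification summary."""
        lines = [
            "Gaze/saccade classification",
            "===========================",
            f"segmentation: {self.model.segmentation}  "
            f"(k={self.model.k}, boundaries={len(self.segments)})",
            f"samples: {len(self.recording)}  "
            f"duration: {self.recording.duration:.1f} s",
        ]
        stats = self.duration_stats()
        for kind in stats.index:
            row = stats.loc[kind]
            lines.append(
                f"{kind:>16}: n={int(row['n']):5d}  "
                f"median {row['median'] * 1000:6.1f} ms  "
                f"IQR {row['q1'] * 1000:6.1f}-{row['q3'] * 1000:6.1f} ms"
            )
        shares = self.time_shares()
        if shares:
            lines.append(
                "time shares: "
                + "  ".join(f"{k} {100 * v:.1f}%" for k, v in sorted(shares.items()))
            )
        r, n = self.main_sequence()
        if r is not None:
            lines.append(f"main sequence: r={r:.3f} over {n} saccades")
        return "\n".join(lines)

    def plot(self, ax=None, tmin=None, tmax=None):
        from .plotting import plot_classification

        return plot_classification(self, ax=ax, tmin=tmin, tmax=tmax)


class FixationModel:
    """Gaze-onset-locked EEG analysis for one channel.

    Wraps epoch extraction (onsets mapped through ``clock``), fERP
    averaging, Morlet fERSP with dB baseline, and the shift-correlation
    time-sensitivity analysis.
    """

    def __init__(
        self,
        eeg: EEGRecording,
        onsets_et: np.ndarray,
        clock: ClockModel,
        *,
        channel: int | str = 0,
        et_rate: float = 90.0,
        erp_window: tuple[float, float] = (-0.200, 0.500),
        tf_window: tuple[float, float] = (-0.875, 1.175),
        tf_crop: tuple[float, float] = (-0.500, 0.800),
        baseline: tuple[float, float] = (-0.500, -0.200),
        freqs: np.ndarray | None = None,
        cycles: float = 3.0,
    ) -> None:
        self.eeg = eeg
        self.onsets_et = np.asarray(onsets_et, dtype=float)
        self.clock = clock
        self.channel = channel
        self.et_rate = et_rate
        self.erp_window = erp_window
        self.tf_window = tf_window
        self.tf_crop = tf_crop
        self.baseline = baseline
        self.freqs = freqs
        self.cycles = cycles

    def _onset_indices(self) -> np.ndarray:
        idx, ok = map_onsets_to_eeg(
            self.onsets_et, self.clock, self.eeg.rate, self.eeg.n_times
        )
        return idx[ok]

    def fit(self, *, ersp: bool = True) -> "FixationResult":
        idx = self._onset_indices()
        erp_epochs = feeg.extract_epochs(self.eeg, idx, self.erp_window)
        ch = (
            self.eeg.channels.index(self.channel)
            if isinstance(self.channel, str)
            else self.channel
        )
        erp = feeg.average_erp(erp_epochs)[ch]
        result = FixationResult(
            model=self,
            erp=erp,
            erp_times=erp_epochs.times,
            n_trials=erp_epochs.n_trials,
            dropped=erp_epochs.dropped,
        )
        if ersp:
            tf_epochs = feeg.extract_epochs(self.eeg, idx, self.tf_window)
            tf = feeg.morlet_tf(
                tf_epochs,
                freqs=self.freqs,
                cycles=self.cycles,
                channel=ch,
                crop=self.tf_crop,
            )
            result.ersp_db = feeg.db_baseline(tf.average(), self.baseline)
        return result

    def shift_correlation(self, mode: str = "erp", shifts=(-1, 0, 1), **kwargs):
        """Per-shift distributions of trial-vs-average Pearson r."""
        return feeg.shift_correlation(
            self.eeg,
            self.onsets_et,
            self.clock,
            et_rate=self.et_rate,
            mode=mode,
            shifts=shifts,
            channel=self.channel,
            window=self.erp_window,
            tf_window=self.tf_window,
            freqs=self.freqs,
            cycles=self.cycles,
            **kwargs,
        )


@dataclass
class FixationResult:
    """fERP/fERSP estimates for one channel."""

    model: FixationModel
    erp: np.ndarray
    erp_times: np.ndarray
    n_trials: int
    dropped: int
    ersp_db: "feeg.TimeFrequencyMap | None" = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Fixation-onset EEG analysis",
            "===========================",
            f"trials: {self.n_trials}  (dropped at edges: {self.dropped})",
            f"ERP window: {self.erp_times[0] * 1000:.0f}..{self.erp_times[-1] * 1000:.0f} ms",
            f"ERP peak: {self.erp.max():.3f} uV at "
            f"{self.erp_times[int(np.argmax(self.erp))] * 1000:.0f} ms",
        ]
        if self.ersp_db is not None:
            tf = self.ersp_db
            i, j = np.unravel_index(np.argmin(tf.power), tf.power.shape)
            lines.append(
                f"ERSP: {tf.freqs[0]:.1f}-{tf.freqs[-1]:.1f} Hz, "
                f"strongest suppression {tf.power[i, j]:.2f} dB at "
                f"{tf.freqs[i]:.1f} Hz / {tf.times[j] * 1000:.0f} ms"
            )
        return "\n".join(lines)

    def plot_erp(self, ax=None):
        from .plotting import plot_erp

        return plot_erp(self, ax=ax)

    def plot_ersp(self, ax=None):
        from .plotting import plot_ersp

        return plot_ersp(self, ax=ax)
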