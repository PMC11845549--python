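import numpy as np
import pytest

from vrgaze.kinematics import VelocitySeries
from vrgaze.segment_classify import (
    EventSequence,
    OculomotorEvent,
    SegmentSet,
    assign_gaze_object,
    build_events,
    classify_samples,
    data_driven_boundaries,
    fixed_boundaries,
    mad_threshold,
    merge_short_events,
    reject_invalid_overlap,
    reject_long_outliers,
)
from vrgaze.io import Provenance

from conftest import make_recording


def vs_from(w, rate=90.0, valid=None):
    w = np.asarray(w, dtype=float)
    if valid is None:
        valid = np.ones(w.size, bool)
    return VelocitySeries(
        t=np.arange(w.size) / rate,
        w=w,
        valid=np.asarray(valid, bool),
        dt=np.full(w.size, 1.0 / rate),
    )


class TestMadThreshold:
    def test_constant_series(self):
        assert mad_threshold(np.full(10, 7.0), k=3) == 7.0

    def test_hand_arithmetic(self):
        # median 5, MAD 2, threshold 5 + 3*2 = 11
        assert mad_threshold(np.arange(1.0, 10.0), k=3) == 11.0

    def test_fewer_than_three_values_falls_back(self):
        assert mad_threshold(np.array([1.0, 2.0]), k=3) is None

    def test_bounded_influence_of_one_outlier(self):
        base = np.arange(1.0, 10.0)
        spiked = base.copy()
        spiked[-1] = 1e6
        # a single huge outlier moves the threshold by at most k * dMAD
        assert abs(mad_threshold(spiked, 3) - mad_threshold(base, 3)) <= 3 * 2.0


class TestBoundaries:
    def _bursty(self, duration_s, n_bursts, rate=90.0):
        n = int(duration_s * rate)
        w = np.full(n, 10.0)
        w += np.linspace(0, 1, n)  # avoid a degenerate MAD of zero
        starts = np.linspace(5, n - 10, n_bursts).astype(int)
        for s in starts:
            w[s : s + 3] = [300.0, 500.0, 300.0]
        return vs_from(w, rate)

    def test_enough_runs_yields_2hz_boundaries(self):
        vs = self._bursty(60.0, 150)
        segs = data_driven_boundaries(vs)
        assert len(segs) == int(round(2 * vs.duration))

    def test_no_suprathreshold_runs_single_segment(self):
        segs = data_driven_boundaries(vs_from(np.linspace(10, 11, 900)))
        assert len(segs) == 0

    def test_fewer_runs_than_target_uses_all(self):
        vs = self._bursty(60.0, 40)
        segs = data_driven_boundaries(vs)
        assert len(segs) == 40

    def test_boundary_sits_on_run_peak(self):
        w = np.full(200, 10.0)
        w += np.linspace(0, 1, 200)
        w[50:55] = [200, 400, 800, 400, 200]
        vs = vs_from(w)
        segs = data_driven_boundaries(vs)
        assert vs.t[52] in segs.boundaries

    def test_fixed_35s_recording(self):
        rec = make_recording(np.arange(0, 35.01, 1 / 90))
        segs = fixed_boundaries(rec)
        np.testing.assert_allclose(segs.boundaries, [10.0, 20.0, 30.0])

    def test_fixed_short_recording_no_boundaries(self):
        rec = make_recording(np.arange(0, 5, 1 / 90))
        assert len(fixed_boundaries(rec)) == 0

    @pytest.mark.parametrize("dur", [9.9, 20.0, 73.4])
    def test_fixed_count_is_floor_duration_over_10(self, dur):
        rec = make_recording(np.arange(0, dur, 1 / 90))
        assert len(fixed_boundaries(rec)) == int(rec.duration // 10)


class TestClassify:
    def test_brute_force_comparison(self):
        w = np.array([10.0, 10, 300, 400, 10, 10])
        vs = vs_from(w)
        labels, thrs = classify_samples(vs, SegmentSet(np.empty(0), "fixed_10s"), k=3)
        thr = thrs[0]
        expected = np.where(w > thr, "saccade", "gaze")
        np.testing.assert_array_equal(labels.astype(str), expected)
        assert list(labels) == ["gaze", "gaze", "saccade", "saccade", "gaze", "gaze"]

    def test_all_equal_velocities_all_gaze(self):
        labels, _ = classify_samples(
            vs_from(np.full(10, 42.0)), SegmentSet(np.empty(0), "fixed_10s")
        )
        assert set(labels) == {"gaze"}

    def test_labels_depend_only_on_own_segment(self):
        # one calm and one violent segment: the calm segment's labels must
        # not change when the violent one gets noisier
        w1 = np.concatenate([np.linspace(10, 12, 45), np.linspace(100, 400, 45)])
        w2 = np.concatenate([np.linspace(10, 12, 45), np.linspace(100, 900, 45)])
        segs = SegmentSet(np.array([0.5]), "fixed_10s")
        l1, _ = classify_samples(vs_from(w1), segs)
        l2, _ = classify_samples(vs_from(w2), segs)
        np.testing.assert_array_equal(l1[:45], l2[:45])

    def test_invalid_intervals_labelled_invalid(self):
        valid = np.ones(8, bool)
        valid[3] = False
        labels, _ = classify_samples(
            vs_from(np.full(8, 10.0), valid=valid),
            SegmentSet(np.empty(0), "fixed_10s"),
        )
        assert labels[3] == "invalid"


class TestBuildAndMerge:
    def test_three_events_from_alternating_labels(self):
        labels = np.array(["gaze", "gaze", "saccade", "saccade", "gaze"], object)
        rec = make_recording(np.arange(6) / 90.0)
        seq = build_events(labels, rec)
        assert [e.kind for e in seq.events] == ["gaze", "saccade", "gaze"]

    def test_single_label_single_event(self):
        labels = np.full(5, "gaze", object)
        rec = make_recording(np.arange(6) / 90.0)
        seq = build_events(labels, rec)
        assert len(seq) == 1
        assert seq.events[0].t_on == 0.0

    def test_events_tile_without_overlap(self):
        labels = np.array(
            ["gaze", "saccade", "saccade", "gaze", "invalid", "gaze"], object
        )
        rec = make_recording(np.arange(7) / 90.0)
        seq = build_events(labels, rec)
        for a, b in zip(seq.events, seq.events[1:]):
            assert a.t_off == b.t_on
        assert seq.events[0].t_on == rec.t[0]

    def test_short_saccade_between_gazes_fuses_all(self):
        # [gaze 100ms][saccade 11ms][gaze 100ms] -> single gaze ~211ms
        seq = EventSequence(
            events=[
                OculomotorEvent("gaze", 0.0, 0.100),
                OculomotorEvent("saccade", 0.100, 0.111),
                OculomotorEvent("gaze", 0.111, 0.211),
            ]
        )
        out = merge_short_events(seq)
        assert len(out) == 1
        assert out.events[0].kind == "gaze"
        assert out.events[0].duration == pytest.approx(0.211)

    def test_plausible_events_untouched(self):
        seq = EventSequence(
            events=[
                OculomotorEvent("gaze", 0.0, 0.100),
                OculomotorEvent("saccade", 0.100, 0.130),
            ]
        )
        out = merge_short_events(seq)
        assert [e.duration for e in out.events] == [pytest.approx(0.1), pytest.approx(0.03)]

    def test_leading_short_saccade_absorbed_forward(self):
        seq = EventSequence(
            events=[
                OculomotorEvent("saccade", 0.0, 0.011),
                OculomotorEvent("gaze", 0.011, 0.211),
            ]
        )
        out = merge_short_events(seq)
        assert len(out) == 1
        assert out.events[0].kind == "gaze"
        assert out.events[0].t_on == 0.0


class TestOutliers:
    def test_extreme_duration_flagged(self):
        events = [
            OculomotorEvent("gaze", i * 0.2, i * 0.2 + 0.1) for i in range(9)
        ]
        events.append(OculomotorEvent("gaze", 2.0, 12.0))
        seq = reject_long_outliers(EventSequence(events=events))
        kinds = [e.kind for e in seq.events]
        assert kinds[:-1] == ["gaze"] * 9
        assert kinds[-1] == "outlier_gaze"

    def test_all_equal_durations_none_flagged(self):
        events = [OculomotorEvent("saccade", i * 0.1, i * 0.1 + 0.05) for i in range(6)]
        seq = reject_long_outliers(EventSequence(events=events))
        assert all(e.kind == "saccade" for e in seq.events)

    def test_pooling_across_sequences_is_order_invariant(self):
        def mk(offset):
            evs = [
                OculomotorEvent("gaze", offset + i * 0.3, offset + i * 0.3 + 0.1 + 0.01 * i)
                for i in range(5)
            ]
            evs.append(OculomotorEvent("gaze", offset + 2.0, offset + 4.0))
            return EventSequence(events=evs)

        a1, b1 = reject_long_outliers([mk(0.0), mk(10.0)])
        b2, a2 = reject_long_outliers([mk(10.0), mk(0.0)])
        assert [e.kind for e in a1.events] == [e.kind for e in a2.events]
        assert [e.kind for e in b1.events] == [e.kind for e in b2.events]


class TestObjectAndInvalid:
    def test_modal_object(self):
        rec = make_recording(np.arange(4) / 90.0)
        rec.hit_object[:] = ["A", "A", "B", "A"]
        seq = EventSequence(events=[OculomotorEvent("gaze", 0.0, 0.05, i_on=0, i_off=2)])
        assign_gaze_object(seq, rec)
        assert seq.events[0].hit_object == "A"

    def test_tie_breaks_to_first_seen(self):
        rec = make_recording(np.arange(3) / 90.0)
        rec.hit_object[:] = ["A", "B", None]
        seq = EventSequence(events=[OculomotorEvent("gaze", 0.0, 0.03, i_on=0, i_off=2)])
        assign_gaze_object(seq, rec)
        assert seq.events[0].hit_object == "A"

    def test_all_absent_stays_absent(self):
        rec = make_recording(np.arange(3) / 90.0)
        rec.hit_object[:] = None
        seq = EventSequence(events=[OculomotorEvent("gaze", 0.0, 0.03, i_on=0, i_off=2)])
        assign_gaze_object(seq, rec)
        assert seq.events[0].hit_object is None

    def test_event_over_untouched_invalid_run_rejected(self):
        valid = np.ones(6, bool)
        valid[2:4] = False
        rec = make_recording(np.arange(6) / 90.0, valid=valid)
        seq = EventSequence(events=[OculomotorEvent("gaze", 0.0, 0.07, i_on=0, i_off=5)])
        reject_invalid_overlap(seq, rec)
        assert seq.events[0].kind == "invalid"

    def test_event_over_interpolated_samples_retained(self):
        rec = make_recording(np.arange(6) / 90.0)
        rec.provenance[2:4] = Provenance.INTERPOLATED
        seq = EventSequence(events=[OculomotorEvent("gaze", 0.0, 0.07, i_on=0, i_off=5)])
        reject_invalid_overlap(seq, rec)
        assert seq.events[0].kind == "gaze"
        assert seq.events[0].eeg_ok

    def test_onset_on_inserted_stamp_disqualified_for_eeg(self):
        rec = make_recording(np.arange(6) / 90.0)
        rec.provenance[0] = Provenance.TIMESTAMP_INTERPOLATED
        seq = EventSequence(events=[OculomotorEvent("gaze", 0.0, 0.07, i_on=0, i_off=5)])
        reject_invalid_overlap(seq, rec)
        assert seq.events[0].kind == "gaze"
        assert not seq.events[0].eeg_ok
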