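import numpy as np
import pytest

from vrgaze.errors import ConfigError, DataError
from vrgaze.fixation_eeg import (
    EpochSet,
    average_erp,
    db_baseline,
    extract_epochs,
    highpass,
    morlet_tf,
    shift_correlation,
)
from vrgaze.io import EEGRecording
from vrgaze.sync import ClockModel


def eeg_from(data, rate=512.0):
    return EEGRecording(data=np.atleast_2d(data), rate=rate, channels=["Oz"])


class TestExtractEpochs:
    def test_index_arithmetic(self):
        eeg = eeg_from(np.arange(8000.0))
        ep = extract_epochs(eeg, [5120], (-0.2, 0.5))
        assert ep.data.shape == (1, 1, 358)  # [5018, 5376)
        assert ep.data[0, 0, 0] == 5018.0
        assert ep.data[0, 0, -1] == 5375.0

    def test_edge_onset_dropped_and_counted(self):
        eeg = eeg_from(np.zeros(1000))
        ep = extract_epochs(eeg, [10, 500], (-0.2, 0.5))
        assert ep.n_trials == 1
        assert ep.dropped == 1

    def test_conservation(self):
        eeg = eeg_from(np.zeros(3000))
        onsets = [5, 150, 1500, 2995]
        ep = extract_epochs(eeg, onsets, (-0.2, 0.5))
        assert ep.n_trials + ep.dropped == len(onsets)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        eeg = eeg_from(rng.standard_normal(5000))
        a = extract_epochs(eeg, [2000, 3000], (-0.1, 0.1))
        b = extract_epochs(eeg, [2007, 3007], (-0.1, 0.1))
        np.testing.assert_array_equal(a.data[:, :, 7:], b.data[:, :, :-7])


class TestAverage:
    def test_identical_trials(self):
        trial = np.sin(np.linspace(0, 3, 100))
        ep = EpochSet(
            data=np.tile(trial, (5, 1, 1)),
            times=np.linspace(0, 1, 100),
            rate=100.0,
            onsets=np.arange(5),
        )
        np.testing.assert_allclose(average_erp(ep)[0], trial)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 2, 50))
        ep = EpochSet(data=data, times=np.arange(50), rate=1.0, onsets=np.arange(10))
        scaled = EpochSet(data=3 * data, times=ep.times, rate=1.0, onsets=ep.onsets)
        np.testing.assert_allclose(average_erp(scaled), 3 * average_erp(ep))

    def test_zero_trials_error(self):
        ep = EpochSet(
            data=np.empty((0, 1, 10)), times=np.arange(10), rate=1.0, onsets=np.empty(0)
        )
        with pytest.raises(DataError):
            average_erp(ep)

    def test_template_recovered_from_noise(self, rng):
        t = np.linspace(-0.2, 0.5, 358)
        template = np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
        trials = template + rng.standard_normal((500, 358)) * 1.1
        ep = EpochSet(
            data=trials[:, None, :], times=t, rate=512.0, onsets=np.arange(500)
        )
        avg = average_erp(ep)[0]
        assert np.corrcoef(avg, template)[0, 1] > 0.95


class TestHighpass:
    def test_dc_removed(self):
        eeg = eeg_from(np.full(4096, 7.0))
        out = highpass(eeg, 5.0)
        assert np.abs(out.data).max() < 0.1

    def test_passband_preserved(self):
        t = np.arange(8192) / 512.0
        eeg = eeg_from(np.sin(2 * np.pi * 20.0 * t))
        out = highpass(eeg, 5.0)
        mid = out.data[0, 2000:6000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        t = np.arange(8192) / 512.0
        eeg = eeg_from(np.sin(2 * np.pi * 1.0 * t))
        out = highpass(eeg, 5.0)
        assert np.abs(out.data[0, 2000:6000]).max() < 0.1  # > 20 dB down

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            highpass(eeg_from(np.zeros(100), rate=100.0), 60.0)


def _sine_epochs(freq, n_trials=3, amp=1.0, rate=512.0, dur=2.05, rng=None):
    t = np.arange(int(dur * rate)) / rate - 0.875
    data = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(data, (n_trials, 1, 1))
    if rng is not None:
        data = data + 0.01 * rng.standard_normal(data.shape)
    return EpochSet(data=data, times=t, rate=rate, onsets=np.arange(n_trials))


class TestMorlet:
    def test_peak_at_sinusoid_frequency(self):
        tf = morlet_tf(_sine_epochs(10.0), crop=(-0.5, 0.8))
        mean_over_time = tf.average().power.mean(axis=1)
        assert tf.freqs[np.argmax(mean_over_time)] == pytest.approx(10.0)

    def test_power_scales_quadratically(self):
        tf1 = morlet_tf(_sine_epochs(10.0, amp=1.0), crop=(-0.3, 0.3))
        tf2 = morlet_tf(_sine_epochs(10.0, amp=2.0), crop=(-0.3, 0.3))
        i = np.argmin(np.abs(tf1.freqs - 10.0))
        ratio = tf2.average().power[i].mean() / tf1.average().power[i].mean()
        assert ratio == pytest.approx(4.0, rel=1e-3)

    def test_white_noise_spectrum_flat_after_bandwidth_scaling(self, rng):
        n, rate = 4096, 512.0
        data = rng.standard_normal((8, 1, n))
        ep = EpochSet(
            data=data, times=np.arange(n) / rate - 2.0, rate=rate, onsets=np.arange(8)
        )
        freqs = np.arange(10.0, 40.0, 2.0)
        tf = morlet_tf(ep, freqs=freqs, crop=(-1.0, 1.0))
        mean_p = tf.average().power.mean(axis=1)
        # amplitude-normalised wavelets pass white noise with expected power
        # proportional to their bandwidth (~f); after that scaling it is flat
        scaled = mean_p / freqs
        scaled /= scaled.mean()
        assert np.all(np.abs(scaled - 1.0) < 0.25)

    def test_epoch_shorter_than_wavelet_rejected(self):
        ep = _sine_epochs(10.0, dur=0.5)
        with pytest.raises(DataError):
            morlet_tf(ep, freqs=np.array([2.0]), crop=None)

    def test_agrees_with_mne_oracle(self):
        # independent implementation check at frequencies where mne's longer
        # (+-5 sigma) wavelets also fit in the epoch
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        rate, n = 512.0, int(3.0 * 512)
        data = rng.standard_normal((2, 1, n))
        ep = EpochSet(
            data=data, times=np.arange(n) / rate - 1.5, rate=rate, onsets=np.arange(2)
        )
        freqs = np.arange(8.0, 30.0, 2.0)
        ours = morlet_tf(ep, freqs=freqs, crop=None)
        theirs = mne.time_frequency.tfr_array_morlet(
            ep.data, sfreq=ep.rate, freqs=freqs, n_cycles=3.0, output="power",
            zero_mean=True,
        )[:, 0]
        mid = slice(600, 1000)
        for fi in range(freqs.size):
            a = ours.power[0, fi, mid]
            b = theirs[0, fi, mid]
            r = np.corrcoef(a, b)[0, 1]
            assert r > 0.999  # identical shape; normalisation differs


class TestDbBaseline:
    def _tf(self, scale_post=1.0):
        ep = _sine_epochs(10.0, n_trials=1)
        tf = morlet_tf(ep, freqs=np.arange(8.0, 13.0), crop=(-0.6, 0.6))
        tf = tf.average()
        if scale_post != 1.0:
            tf.power[:, tf.times >= 0] *= scale_post
        return tf

    def test_stationary_process_near_zero_db(self):
        out = db_baseline(self._tf(), baseline=(-0.5, -0.2))
        assert np.abs(out.power).max() < 0.5

    def test_doubling_gives_3db(self):
        out = db_baseline(self._tf(scale_post=2.0), baseline=(-0.5, -0.2))
        post = out.power[:, out.times >= 0.05]
        assert np.median(post) == pytest.approx(10 * np.log10(2), abs=0.1)

    def test_tenth_gives_minus_10db(self):
        out = db_baseline(self._tf(scale_post=0.1), baseline=(-0.5, -0.2))
        post = out.power[:, out.times >= 0.05]
        assert np.median(post) == pytest.approx(-10.0, abs=0.1)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ConfigError):
            db_baseline(self._tf(), baseline=(-5.0, -4.0))


class TestShiftCorrelation:
    def test_single_trial_identical_to_average(self, rng):
        rate = 512.0
        n = int(40 * rate)
        t = np.arange(n) / rate
        sig = rng.standard_normal(n)
        eeg = EEGRecording(data=sig[None, :], rate=rate, channels=["Oz"])
        model = ClockModel(offset=0.0, drift_total=0.0, t0_et=0.0, t1_et=40.0)
        onsets = np.array([10.0, 20.0])
        rs = shift_correlation(
            eeg, onsets, model, mode="erp", shifts=(0,), hp_cutoff=None
        )
        # each trial correlates with the 2-trial average equally; with two
        # independent noise trials r is strictly between 0 and 1, and a trial
        # against itself alone would be exactly 1
        only = shift_correlation(
            eeg, onsets[:1].repeat(2), model, mode="erp", shifts=(0,), hp_cutoff=None
        )
        np.testing.assert_allclose(only[0], 1.0, atol=1e-12)
        assert rs[0].shape == (2,)

    def test_fewer_than_two_trials_rejected(self):
        eeg = EEGRecording(data=np.zeros((1, 5000)), rate=512.0, channels=["Oz"])
        model = ClockModel(offset=0.0, drift_total=0.0, t0_et=0.0, t1_et=5.0)
        with pytest.raises(DataError):
            shift_correlation(eeg, np.array([2.0]), model, mode="erp", hp_cutoff=None)
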