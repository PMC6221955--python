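import numpy as np
import pytest

from emobio.preprocess import (
    EpochSet,
    bandpass,
    baseline_correct,
    compute_erp,
    epoch,
    notch,
    reject_bad_epochs,
    rereference_average,
)
from tests.conftest import make_recording


def spectral_amplitude(x, freq, rate):
    """FFT oracle: amplitude of the sinusoidal component nearest `freq`."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2 / n
    freqs = np.fft.rfftfreq(n, 1 / rate)
    return spec[np.argmin(np.abs(freqs - freq))]


@pytest.fixture
def sine_rec(mini_montage):
    rate = 1000.0
    t = np.arange(0, 10, 1 / rate)
    data = np.vstack([np.sin(2 * np.pi * f * t) for f in (10.0, 50.0, 0.3, 10.0)])
    return make_recording(mini_montage, data, rate_hz=rate)


class TestBandpass:
    def test_dc_removed(self, mini_montage):
        rec = make_recording(mini_montage, np.full((4, 5000), 5.0), rate_hz=1000.0)
        out = bandpass(rec, 1.0, 100.0)
        assert np.mean(out.data**2) < 0.01 * np.mean(rec.data**2)

    def test_passband_sinusoid_preserved(self, sine_rec):
        out = bandpass(sine_rec, 1.0, 100.0)
        amp = spectral_amplitude(out.data[0], 10.0, sine_rec.rate_hz)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self, mini_montage):
        rate = 1000.0
        t = np.arange(0, 20, 1 / rate)
        x = np.sin(2 * np.pi * 150.0 * t)  # at 1.5x the 100 Hz edge
        rec = make_recording(mini_montage, np.tile(x, (4, 1)), rate_hz=rate)
        out = bandpass(rec, 1.0, 100.0)
        amp = spectral_amplitude(out.data[0], 150.0, rate)
        assert amp < 10 ** (-20 / 20)  # >= 20 dB down

    def test_length_preserved(self, sine_rec):
        assert bandpass(sine_rec, 1.0, 100.0).n_samples == sine_rec.n_samples

    def test_nyquist_violation(self, sine_rec):
        with pytest.raises(ValueError, match="band edges"):
            bandpass(sine_rec, 1.0, 600.0)

    def test_linearity(self, mini_montage):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 4, 4000))
        rate = 250.0
        fx = bandpass(make_recording(mini_montage, x, rate), 1.0, 40.0).data
        fy = bandpass(make_recording(mini_montage, y, rate), 1.0, 40.0).data
        fxy = bandpass(make_recording(mini_montage, 2 * x + 3 * y, rate), 1.0, 40.0).data
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, rtol=1e-6, atol=1e-9)


class TestNotch:
    def test_50hz_attenuated(self, sine_rec):
        out = notch(sine_rec)
        amp = spectral_amplitude(out.data[1], 50.0, sine_rec.rate_hz)
        assert amp <= 0.1

    def test_10hz_preserved(self, sine_rec):
        out = notch(sine_rec)
        amp = spectral_amplitude(out.data[0], 10.0, sine_rec.rate_hz)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_defaults(self, sine_rec):
        from emobio.preprocess import DEFAULT_NOTCH

        assert DEFAULT_NOTCH == (47.5, 52.5)


class TestAverageReference:
    def test_two_channel_example(self, mini_montage):
        data = np.array([[1.0], [3.0], [2.0], [2.0]])
        out = rereference_average(make_recording(mini_montage, data))
        np.testing.assert_allclose(out.data[:2, 0], [-1.0, 1.0])

    def test_column_means_zero(self, mini_montage):
        rng = np.random.default_rng(1)
        rec = make_recording(mini_montage, rng.standard_normal((4, 100)))
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_idempotent(self, mini_montage):
        rng = np.random.default_rng(2)
        rec = make_recording(mini_montage, rng.standard_normal((4, 50)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_pairwise_differences_preserved(self, mini_montage):
        rng = np.random.default_rng(3)
        rec = make_recording(mini_montage, rng.standard_normal((4, 50)))
        out = rereference_average(rec)
        np.testing.assert_allclose(
            out.data[0] - out.data[2], rec.data[0] - rec.data[2], atol=1e-12
        )

    def test_excludes_bad_channels(self, mini_montage):
        rec = make_recording(mini_montage, np.array([[1.0], [3.0], [2.0], [100.0]]))
        rec.bad_channels = frozenset({"Oz"})
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data[:3, 0].mean(), 0.0, atol=1e-12)

    def test_all_bad_raises(self, mini_montage):
        rec = make_recording(mini_montage, np.ones((4, 5)))
        rec.bad_channels = frozenset(mini_montage.channel_names)
        with pytest.raises(ValueError, match="good channels"):
            rereference_average(rec)


class TestEpoch:
    def test_visual_epoch_shape(self, montage64):
        # 240 onset events at 1000 Hz, window (-100, 900) -> 240 x 64 x 1000
        rate = 1000.0
        n = 26_000  # overlapping windows are fine for a shape check
        events = [("happy/morph", 1000 + i * 100) for i in range(240)]
        rec = make_recording(montage64, np.zeros((64, n)), rate, events)
        ep = epoch(rec, "morph", -100.0, 900.0)
        assert ep.tensor.shape == (240, 64, 1000)

    def test_impulse_alignment(self, mini_montage):
        data = np.zeros((4, 2000))
        data[:, 500] = 7.0
        rec = make_recording(mini_montage, data, 1000.0, [("x/stim", 500)])
        ep = epoch(rec, "stim", -100.0, 900.0)
        assert ep.tensor[0, 0, 100] == 7.0
        assert np.count_nonzero(ep.tensor[0, 0]) == 1

    def test_no_matching_events(self, mini_montage):
        rec = make_recording(mini_montage, np.zeros((4, 100)), 250.0, [])
        ep = epoch(rec, "stim", -10.0, 10.0)
        assert ep.n_trials == 0

    def test_out_of_bounds_trial_dropped(self, mini_montage, caplog):
        events = [("a/stim", 2), ("a/stim", 500)]
        rec = make_recording(mini_montage, np.zeros((4, 1000)), 1000.0, events)
        with caplog.at_level("WARNING"):
            ep = epoch(rec, "stim", -100.0, 100.0)
        assert ep.n_trials == 1
        assert "dropped" in caplog.text

    def test_condition_labels_parsed(self, mini_montage):
        events = [("happy/stim", 50), ("sad/stim", 150)]
        rec = make_recording(mini_montage, np.zeros((4, 400)), 250.0, events)
        ep = epoch(rec, "stim", 0.0, 100.0)
        assert list(ep.conditions) == ["happy", "sad"]

    def test_concatenation_reconstructs_exactly(self, mini_montage):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((4, 1000))
        rec = make_recording(mini_montage, data, 1000.0, [("a/stim", 300)])
        left = epoch(rec, "stim", 0.0, 100.0)
        right = epoch(rec, "stim", 100.0, 200.0)
        joined = np.concatenate([left.tensor[0], right.tensor[0]], axis=1)
        np.testing.assert_array_equal(joined, data[:, 300:500])


def reject_oracle(tensor, abs_uV, prob_z):
    """Independent brute-force reimplementation of both rejection criteria."""
    n_trials, n_chan, _ = tensor.shape
    extreme = [np.max(np.abs(tensor[t])) > abs_uV for t in range(n_trials)]
    jp = []
    for t in range(n_trials):
        total = 0.0
        for c in range(n_chan):
            mu = tensor[:, c, :].mean()
            sd = tensor[:, c, :].std()
            if sd == 0:
                sd = 1.0
            z = (tensor[t, c] - mu) / sd
            total += np.mean(-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2 * np.pi))
        jp.append(total)
    jp = np.asarray(jp)
    sd = jp.std()
    improbable = (
        np.abs(jp - jp.mean()) > prob_z * sd if sd > 0 else np.zeros(n_trials, bool)
    )
    return np.asarray(extreme) | improbable


def make_epochs(tensor, conditions=None, rate=250.0):
    tensor = np.asarray(tensor, dtype=float)
    n = tensor.shape[0]
    return EpochSet(
        tensor=tensor,
        rate_hz=rate,
        window_ms=(-100.0, -100.0 + tensor.shape[2] / rate * 1000.0),
        conditions=np.array(conditions or ["a"] * n, dtype=object),
        channel_names=tuple(f"ch{i}" for i in range(tensor.shape[1])),
    )


class TestRejectBadEpochs:
    def test_spike_rejected(self):
        rng = np.random.default_rng(0)
        tensor = rng.standard_normal((10, 3, 100))
        tensor[4, 1, 50] = 500.0
        out = reject_bad_epochs(make_epochs(tensor), abs_uV=100.0, prob_z=5.0)
        assert out.rejected[4]
        assert out.rejected.sum() == 1

    def test_identical_trials_not_rejected(self):
        tensor = np.tile(np.sin(np.linspace(0, 6, 100)), (8, 2, 1))
        out = reject_bad_epochs(make_epochs(tensor), abs_uV=100.0, prob_z=1.0)
        assert not out.rejected.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        tensor = rng.standard_normal((20, 4, 60))
        tensor[3] *= 40.0  # improbable trial
        tensor[11, 2, 10] = 150.0  # extreme value
        ep = make_epochs(tensor)
        out = reject_bad_epochs(ep, abs_uV=100.0, prob_z=2.0)
        np.testing.assert_array_equal(out.rejected, reject_oracle(tensor, 100.0, 2.0))

    def test_data_preserved(self):
        rng = np.random.default_rng(6)
        tensor = rng.standard_normal((5, 2, 30))
        ep = make_epochs(tensor)
        out = reject_bad_epochs(ep, abs_uV=0.5, prob_z=1.0)
        np.testing.assert_array_equal(out.tensor, tensor)

    def test_invalid_thresholds(self):
        ep = make_epochs(np.zeros((2, 2, 10)))
        with pytest.raises(ValueError):
            reject_bad_epochs(ep, abs_uV=-1.0, prob_z=5.0)


class TestBaselineCorrect:
    def test_constant_trial_zeroed(self):
        ep = make_epochs(np.full((3, 2, 100), 5.0))
        out = baseline_correct(ep, -100.0, 0.0)
        np.testing.assert_allclose(out.tensor, 0.0, atol=1e-12)

    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(7)
        ep = make_epochs(rng.standard_normal((6, 3, 100)))
        out = baseline_correct(ep, -100.0, 0.0)
        lo, hi = out.ms_to_index(-100.0), out.ms_to_index(0.0)
        np.testing.assert_allclose(
            out.tensor[:, :, lo:hi].mean(axis=2), 0.0, atol=1e-9
        )

    def test_linear_ramp_closed_form(self):
        rate = 250.0
        n = 100
        ramp = np.arange(n, dtype=float)
        ep = make_epochs(np.tile(ramp, (1, 1, 1)), rate=rate)
        lo, hi = ep.ms_to_index(-100.0), ep.ms_to_index(0.0)
        expected = ramp - ramp[lo:hi].mean()
        out = baseline_correct(ep, -100.0, 0.0)
        np.testing.assert_allclose(out.tensor[0, 0], expected, atol=1e-12)

    def test_empty_baseline_raises(self):
        ep = make_epochs(np.zeros((2, 2, 50)))
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(ep, 0.0, 0.0)


class TestComputeErp:
    def test_mean_of_two(self):
        tensor = np.stack([np.ones((2, 10)), 3 * np.ones((2, 10))])
        erp = compute_erp(make_epochs(tensor), "a")
        np.testing.assert_allclose(erp, 2.0)

    def test_rejected_excluded(self):
        tensor = np.stack([np.ones((2, 10)), 3 * np.ones((2, 10))])
        ep = make_epochs(tensor)
        ep.rejected[1] = True
        np.testing.assert_allclose(compute_erp(ep, "a"), 1.0)

    def test_identical_trials_idempotent(self):
        trial = np.random.default_rng(8).standard_normal((3, 20))
        ep = make_epochs(np.tile(trial, (5, 1, 1)))
        np.testing.assert_allclose(compute_erp(ep, "a"), trial)

    def test_condition_filter(self):
        tensor = np.stack([np.ones((1, 5)), 9 * np.ones((1, 5))])
        ep = make_epochs(tensor, conditions=["a", "b"])
        np.testing.assert_allclose(compute_erp(ep, "b"), 9.0)

    def test_no_survivors_raises(self):
        ep = make_epochs(np.zeros((1, 1, 5)))
        ep.rejected[:] = True
        with pytest.raises(ValueError, match="no surviving"):
            compute_erp(ep, "a")
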