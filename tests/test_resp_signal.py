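"""Signal extraction, conditioning chain and chirp-Z rate estimation."""

import numpy as np
import pytest

from thermoresp.errors import FlatSignalError, SignalTooShortError, ThermorespError
from thermoresp.resp_signal import (
    BandConfig,
    RespSignal,
    bandpass,
    estimate_rr_czt,
    extract_raw_signal,
    filter_chain,
    hampel_filter,
    moving_average,
    normalize,
    sliding_rr,
)
from thermoresp.roi_tracking import ROIBox


def _tone(freq, duration_s=60.0, fs=30.0, amp=1.0, noise=0.0, seed=0):
    t = np.arange(int(duration_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, len(t))
    return RespSignal(values=x, fs=fs)


class TestExtractRawSignal:
    def test_mean_of_patch(self):
        frame = np.array([[30.0, 30.2], [29.8, 30.0]])
        roi = ROIBox(bx=0, by=0, w=2, h=2, coord_frame="thermal")
        sig = extract_raw_signal([frame], [roi], fs=30.0)
        assert sig.values[0] == pytest.approx(30.0)

    def test_constant_frames_constant_signal(self):
        frames = [np.full((8, 8), 31.5)] * 5
        roi = ROIBox(bx=2, by=2, w=3, h=3, coord_frame="thermal")
        sig = extract_raw_signal(frames, [roi] * 5, fs=30.0)
        assert np.allclose(sig.values, 31.5)

    def test_gap_interpolated_flag_kept(self):
        frames = [np.full((4, 4), v) for v in (30.0, 99.0, 30.2)]
        roi = ROIBox(bx=0, by=0, w=4, h=4, coord_frame="thermal")
        sig = extract_raw_signal(frames, [roi, None, roi], fs=30.0)
        assert sig.values[1] == pytest.approx(30.1)
        assert list(sig.valid) == [True, False, True]

    def test_all_invalid_errors(self):
        with pytest.raises(ThermorespError):
            extract_raw_signal([np.zeros((4, 4))], [None], fs=30.0)

    def test_length_mismatch_errors(self):
        roi = ROIBox(bx=0, by=0, w=2, h=2)
        with pytest.raises(ValueError):
            extract_raw_signal([np.zeros((4, 4))] * 3, [roi], fs=30.0)


class TestNormalize:
    def test_zscore_exact(self):
        sig = normalize(RespSignal(values=np.array([1.0, 2.0, 3.0]), fs=1.0))
        assert np.mean(sig.values) == pytest.approx(0.0, abs=1e-15)
        assert np.std(sig.values) == pytest.approx(1.0, abs=1e-15)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        sig = normalize(RespSignal(values=rng.normal(size=100), fs=1.0))
        again = normalize(sig)
        assert np.abs(again.values - sig.values).max() <= 1e-12

    def test_flat_signal_rejected(self):
        with pytest.raises(FlatSignalError):
            normalize(RespSignal(values=np.ones(10), fs=1.0))


class TestHampel:
    def test_spike_replaced_by_median(self):
        sig = RespSignal(values=np.array([1.0, 1, 1, 100, 1, 1, 1]), fs=1.0)
        out = hampel_filter(sig, half_window=3, n_sigma=3)
        assert np.allclose(out.values, 1.0)

    def test_constant_unchanged(self):
        sig = RespSignal(values=np.full(50, 2.5), fs=1.0)
        out = hampel_filter(sig, half_window=5)
        assert np.array_equal(out.values, sig.values)

    def test_clean_sinusoid_barely_touched(self):
        sig = _tone(0.8, duration_s=60)
        out = hampel_filter(sig, half_window=30, n_sigma=3)
        altered = np.mean(out.values != sig.values)
        assert altered <= 0.01

    def test_planted_10sigma_spikes_removed(self):
        rng = np.random.default_rng(1)
        sig = _tone(0.8, duration_s=60, noise=0.1, seed=2)
        x = sig.values.copy()
        spikes = rng.choice(len(x), size=10, replace=False)
        spike_mag = 10 * np.std(x)
        x[spikes] += spike_mag
        out = hampel_filter(RespSignal(values=x, fs=30.0), half_window=30)
        # each spike is knocked back to within 20% of its height of the
        # clean waveform (the local median cannot track a steep sinusoid
        # exactly, but the outlier itself must be gone)
        resid = np.abs(out.values[spikes] - sig.values[spikes])
        assert resid.max() <= 0.2 * spike_mag


class TestMovingAverage:
    def test_centre_value(self):
        sig = RespSignal(values=np.array([0.0, 3.0, 0.0]), fs=1.0)
        assert moving_average(sig, 3).values[1] == pytest.approx(1.0)

    def test_window_one_identity(self):
        sig = RespSignal(values=np.arange(5.0), fs=1.0)
        assert np.array_equal(moving_average(sig, 1).values, sig.values)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(3)
        sig = RespSignal(values=rng.normal(size=2000), fs=30.0)
        out = moving_average(sig, 5)
        assert np.var(out.values) < np.var(sig.values)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(RespSignal(values=np.zeros(5), fs=1.0), 4)


class TestBandpass:
    def test_dc_rejected(self):
        sig = RespSignal(values=np.full(900, 10.0), fs=30.0)
        out = bandpass(sig, BandConfig.adult())
        assert abs(np.mean(out.values)) <= 1e-3 * 10.0

    def test_inband_tone_preserved(self):
        sig = _tone(0.25, duration_s=60)
        out = bandpass(sig, BandConfig.adult())
        mid = slice(300, -300)
        ratio = np.std(out.values[mid]) / np.std(sig.values[mid])
        assert abs(ratio - 1.0) <= 0.10

    def test_out_of_band_attenuation_20db(self):
        band = BandConfig.adult()
        inband = bandpass(_tone(0.25, 60), band)
        outband = bandpass(_tone(5.0, 60), band)
        mid = slice(300, -300)
        db = 20 * np.log10(np.std(outband.values[mid])
                           / np.std(inband.values[mid]))
        assert db <= -20.0

    def test_band_beyond_nyquist_rejected(self):
        sig = _tone(0.25, 60, fs=2.0)
        with pytest.raises(ValueError):
            bandpass(sig, BandConfig(low_hz=0.1, high_hz=1.5))

    def test_zero_phase_no_peak_shift(self):
        band = BandConfig.neonate()
        sig = _tone(0.8, duration_s=30)
        f_raw, _, _ = estimate_rr_czt(sig.values, band, fs=30.0)
        f_filt, _, _ = estimate_rr_czt(bandpass(sig, band).values, band, fs=30.0)
        assert abs(f_raw - f_filt) <= 0.005


class TestCzt:
    def test_48bpm_tone(self):
        sig = _tone(0.8, duration_s=30)
        _, rr, _ = estimate_rr_czt(sig, BandConfig.neonate())
        assert rr == pytest.approx(48.0, abs=0.3)

    def test_noisy_tone_within_1bpm(self):
        # SNR 10 dB: noise sd = amp / sqrt(2 * 10)
        sig = _tone(0.8, duration_s=30, noise=1.0 / np.sqrt(20), seed=5)
        _, rr, _ = estimate_rr_czt(sig, BandConfig.neonate())
        assert abs(rr - 48.0) <= 1.0

    def test_agrees_with_dense_fft_oracle(self):
        band = BandConfig.neonate()
        rng = np.random.default_rng(6)
        fs, res = 30.0, 0.005
        for _ in range(20):
            f0 = rng.uniform(band.low_hz + 0.05, band.high_hz - 0.05)
            t = np.arange(int(30 * fs)) / fs
            x = np.sin(2 * np.pi * f0 * t) + 0.2 * rng.normal(size=len(t))
            f_czt, _, _ = estimate_rr_czt(x, band, freq_resolution=res, fs=fs)
            n_fft = 2**19
            spec = np.abs(np.fft.rfft(x - x.mean(), n=n_fft))
            freqs = np.fft.rfftfreq(n_fft, 1 / fs)
            sel = (freqs >= band.low_hz) & (freqs <= band.high_hz)
            f_fft = freqs[sel][np.argmax(spec[sel])]
            assert abs(f_czt - f_fft) <= res

    def test_too_short_window_rejected(self):
        sig = _tone(0.8, duration_s=2)
        with pytest.raises(SignalTooShortError):
            estimate_rr_czt(sig, BandConfig.neonate())


class TestSlidingRr:
    def test_window_arithmetic(self):
        assert len(sliding_rr(_tone(0.8, 90), BandConfig.neonate())) == 4
        assert len(sliding_rr(_tone(0.8, 80), BandConfig.neonate())) == 3

    def test_constant_rate_all_windows(self):
        sig = _tone(0.8, duration_s=90, noise=0.1, seed=7)
        rr = sliding_rr(sig, BandConfig.neonate())
        for w in rr:
            assert abs(w.rr_bpm - 48.0) <= 1.0
            assert w.rr_bpm == pytest.approx(60.0 * w.peak_freq_hz)

    def test_deterministic(self):
        sig = _tone(0.8, duration_s=90, noise=0.2, seed=8)
        a = sliding_rr(sig, BandConfig.neonate())
        b = sliding_rr(sig, BandConfig.neonate())
        assert [w.rr_bpm for w in a] == [w.rr_bpm for w in b]

    def test_short_record_rejected(self):
        with pytest.raises(SignalTooShortError):
            sliding_rr(_tone(0.8, 20), BandConfig.neonate())

    def test_long_gap_flags_low_quality(self):
        sig = _tone(0.8, 90)
        valid = np.ones(len(sig.values), dtype=bool)
        valid[300:400] = False  # 3.3 s gap inside the first window
        gappy = RespSignal(values=sig.values, fs=sig.fs, valid=valid)
        rr = sliding_rr(gappy, BandConfig.neonate())
        assert rr[0].low_quality
        assert not rr[-1].low_quality

    @pytest.mark.parametrize("rate_bpm,band", [
        (15.0, BandConfig.adult()), (30.0, BandConfig.adult()),
        (48.0, BandConfig.neonate()), (72.0, BandConfig.neonate()),
    ])
    def test_rate_recovery_across_bands(self, rate_bpm, band):
        for seed in range(5):
            sig = _tone(rate_bpm / 60.0, duration_s=90,
                        noise=1.0 / np.sqrt(20), seed=seed)
            rr = sliding_rr(sig, band)
            for w in rr:
                assert abs(w.rr_bpm - rate_bpm) <= 1.0
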