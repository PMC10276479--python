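import numpy as np
import pytest

from csfdyn import ContractError, PressureTrace, UnusableTraceError
from csfdyn.icp_waveform import (
    antialias_downsample,
    bandpass_cardiac,
    baseline_icp,
    despike,
    instantaneous_p2p,
    mean_wave_amplitude,
)
from csfdyn.synthetic_data import TraceSpec, gen_icp_trace

from conftest import make_sine_trace


class TestDespike:
    def test_single_spike_masked(self):
        p = np.full(10_000, 4.0)
        p[5000] = 80.0
        trace = PressureTrace.from_samples(p, fs=1000.0)
        res = despike(trace)
        assert res.n_masked >= 1
        assert not np.any(np.abs(res.trace.p[res.trace.mask]) > 50.0)
        # spike bridged back to the constant level
        assert res.trace.p[5000] == pytest.approx(4.0)

    def test_spike_free_identity(self):
        trace = make_sine_trace(4.0, 0.2, duration=10.0, baseline=4.0)
        res = despike(trace)
        assert res.n_masked == 0
        np.testing.assert_array_equal(res.trace.p, trace.p)

    def test_injected_spikes_all_masked(self):
        spec = TraceSpec(duration=60.0, cardiac_p2p=0.1, ventilation_p2p=0.6,
                         noise_sd=0.02, spike_rate_per_min=5.0, seed=11)
        trace, truth = gen_icp_trace(spec)
        res = despike(trace)
        spiked = set(truth.spike_indices.tolist())
        # all injected positions detected (they were bridged => p changed or masked)
        detected = set(np.flatnonzero(trace.p != res.trace.p.round(20)).tolist()) | set(
            np.flatnonzero(~res.trace.mask).tolist()
        )
        assert spiked <= detected
        false_rate = (res.n_masked - len(spiked)) / trace.n_samples
        assert false_rate < 1e-3

    def test_unusable_trace_raises(self):
        p = np.full(1000, 100.0)
        with pytest.raises(UnusableTraceError):
            despike(PressureTrace.from_samples(p, fs=1000.0))

    def test_long_gap_splits_segments(self):
        p = np.full(10_000, 4.0)
        p[2000:3000] = np.nan  # 1 s gap at 1 kHz > 0.5 s bridge limit
        trace = PressureTrace.from_samples(p, fs=1000.0)
        res = despike(trace)
        assert len(res.segments) == 2
        assert not res.trace.mask[2500]


class TestAntialiasDownsample:
    def test_passband_identity(self):
        trace = make_sine_trace(4.0, 2.0, fs=1000.0, duration=30.0)
        out = antialias_downsample(trace, 100.0)
        assert out.fs == 100.0
        interior = out.p[200:-200]
        assert np.ptp(interior) == pytest.approx(2.0, rel=0.01)

    def test_stopband_rejection(self):
        trace = make_sine_trace(300.0, 2.0, fs=1000.0, duration=30.0)
        out = antialias_downsample(trace, 100.0)
        interior = out.p[100:-100]  # exclude boundary-padding transients
        assert np.sqrt(np.mean(interior**2)) < 1e-3 * np.sqrt(np.mean(trace.p**2))

    def test_low_frequency_power_conserved(self, rng):
        # broadband noise: power below 10 Hz conserved within 2% (direct DFT oracle)
        n = 2**16
        fs = 1000.0
        x = rng.normal(0, 1, n)
        trace = PressureTrace.from_samples(x, fs=fs)
        out = antialias_downsample(trace, 100.0)

        def band_power(sig, fs, lo=0.5, hi=10.0):
            spec = np.fft.rfft(sig)
            freqs = np.fft.rfftfreq(len(sig), 1 / fs)
            sel = (freqs >= lo) & (freqs <= hi)
            return np.sum(np.abs(spec[sel]) ** 2) / len(sig) ** 2 * len(sig)

        p_in = band_power(trace.p, fs)
        p_out = band_power(out.p, out.fs) * (len(trace.p) / len(out.p))
        assert p_out == pytest.approx(p_in, rel=0.02)

    def test_fs_out_above_fs_raises(self):
        trace = make_sine_trace(4.0, 1.0, fs=100.0, duration=10.0)
        with pytest.raises(ContractError):
            antialias_downsample(trace, 200.0)


class TestBandpassCardiac:
    def test_inband_identity(self):
        trace = make_sine_trace(4.0, 0.2, fs=100.0, duration=60.0)
        out = bandpass_cardiac(trace)
        assert np.ptp(out.p[500:-500]) == pytest.approx(0.2, rel=0.05)

    def test_ventilation_rejection(self):
        trace = make_sine_trace(1.3, 0.5, fs=100.0, duration=60.0)
        out = bandpass_cardiac(trace)
        assert np.ptp(out.p[500:-500]) < 0.025

    def test_superposition(self):
        t = np.arange(6000) / 100.0
        cardiac = 0.1 * np.sin(2 * np.pi * 4.0 * t)
        vent = 0.25 * np.sin(2 * np.pi * 1.3 * t)
        trace = PressureTrace(t=t, p=cardiac + vent, fs=100.0)
        out = bandpass_cardiac(trace)
        sel = slice(500, -500)
        rms_err = np.sqrt(np.mean((out.p[sel] - cardiac[sel]) ** 2))
        rms_sig = np.sqrt(np.mean(cardiac[sel] ** 2))
        assert rms_err < 0.05 * rms_sig

    def test_too_short_raises(self):
        trace = make_sine_trace(4.0, 0.2, fs=100.0, duration=5.0)
        with pytest.raises(ContractError):
            bandpass_cardiac(trace)

    def test_bad_band_raises(self):
        trace = make_sine_trace(4.0, 0.2, fs=100.0, duration=60.0)
        with pytest.raises(ContractError):
            bandpass_cardiac(trace, 5.5, 1.6)


class TestInstantaneousP2P:
    def test_sinusoid_cycles(self):
        trace = make_sine_trace(4.0, 0.18, fs=100.0, duration=60.0)
        cyc = instantaneous_p2p(trace)
        assert 210 <= len(cyc.amplitudes) <= 240  # ~4 Hz over 56 s interior
        np.testing.assert_allclose(cyc.amplitudes, 0.18, rtol=0.02)

    def test_zero_signal_raises(self):
        trace = PressureTrace.from_samples(np.zeros(6000), fs=100.0)
        with pytest.raises(ContractError):
            instantaneous_p2p(trace)

    def test_amplitude_modulation_tracked(self):
        t = np.arange(6000) / 100.0
        T = t[-1]
        amp = 0.05 + 0.04 * t / T
        trace = PressureTrace(t=t, p=amp * np.sin(2 * np.pi * 4.0 * t), fs=100.0)
        cyc = instantaneous_p2p(trace)
        expected = 2 * (0.05 + 0.04 * cyc.cycle_start_t / T)
        np.testing.assert_allclose(cyc.amplitudes, expected, rtol=0.05)


class TestMeanWaveAmplitude:
    @pytest.mark.parametrize("p2p", [0.10, 0.18])
    def test_recovery_at_printed_levels(self, p2p):
        spec = TraceSpec(duration=120.0, baseline=3.4, cardiac_freq=4.0, cardiac_p2p=p2p,
                         ventilation_p2p=0.6, noise_sd=0.02, seed=7)
        trace, truth = gen_icp_trace(spec)
        res = mean_wave_amplitude(trace)
        assert res.mwa == pytest.approx(truth.mwa, rel=0.05)

    def test_constant_trace_raises(self):
        trace = PressureTrace.from_samples(np.full(120_000, 3.4), fs=1000.0)
        with pytest.raises(ContractError):
            mean_wave_amplitude(trace)

    def test_short_trace_raises(self):
        trace = make_sine_trace(4.0, 0.1, fs=1000.0, duration=30.0)
        with pytest.raises(ContractError):
            mean_wave_amplitude(trace)

    def test_linearity_in_signal_scale(self):
        spec = TraceSpec(duration=90.0, cardiac_p2p=0.1, ventilation_p2p=0.0, noise_sd=0.0)
        trace, _ = gen_icp_trace(spec)
        res1 = mean_wave_amplitude(trace)
        scaled = PressureTrace(t=trace.t, p=trace.p * 3.0, fs=trace.fs)
        res3 = mean_wave_amplitude(scaled)
        assert res3.mwa == pytest.approx(3.0 * res1.mwa, rel=1e-6)

    def test_baseline_shift_invariance(self):
        spec = TraceSpec(duration=90.0, cardiac_p2p=0.1, ventilation_p2p=0.6, noise_sd=0.02, seed=3)
        trace, _ = gen_icp_trace(spec)
        res = mean_wave_amplitude(trace)
        shifted = PressureTrace(t=trace.t, p=trace.p + 7.7, fs=trace.fs)
        res_shift = mean_wave_amplitude(shifted)
        assert abs(res_shift.mwa - res.mwa) < 1e-6

    def test_out_of_band_immunity(self):
        base = TraceSpec(duration=90.0, cardiac_p2p=0.1, ventilation_p2p=0.0, noise_sd=0.0)
        loud = TraceSpec(duration=90.0, cardiac_p2p=0.1, ventilation_p2p=1.0, noise_sd=0.0)
        mwa0 = mean_wave_amplitude(gen_icp_trace(base)[0]).mwa
        mwa1 = mean_wave_amplitude(gen_icp_trace(loud)[0]).mwa
        assert abs(mwa1 - mwa0) / mwa0 < 0.05

    def test_envelope_estimator_agrees(self):
        spec = TraceSpec(duration=120.0, cardiac_p2p=0.18, ventilation_p2p=0.6,
                         noise_sd=0.02, seed=9)
        trace, _ = gen_icp_trace(spec)
        cyc = mean_wave_amplitude(trace, method="cycle").mwa
        env = mean_wave_amplitude(trace, method="envelope").mwa
        assert env == pytest.approx(cyc, rel=0.05)

    def test_mwa_is_mean_of_amplitudes(self):
        trace, _ = gen_icp_trace(TraceSpec(duration=90.0, seed=2))
        res = mean_wave_amplitude(trace)
        assert res.mwa == pytest.approx(float(np.mean(res.amplitudes)), abs=1e-12)
        assert res.mwa >= 0


class TestBaselineICP:
    def test_constant_trace(self):
        trace = PressureTrace.from_samples(np.full(60_000, 5.6), fs=1000.0)
        with pytest.warns(UserWarning):
            assert baseline_icp(trace, window=900.0) == pytest.approx(5.6)

    def test_sinusoid_mean(self):
        # integer number of 4 Hz cycles over 60 s
        trace = make_sine_trace(4.0, 0.18, fs=1000.0, duration=60.0, baseline=3.4)
        assert baseline_icp(trace, window=60.0) == pytest.approx(3.4, abs=1e-3)

    def test_drifting_trace(self):
        spec = TraceSpec(duration=120.0, baseline=5.6, cardiac_p2p=0.18, ventilation_p2p=0.6,
                         drift_amplitude=0.2, noise_sd=0.02, seed=21)
        trace, truth = gen_icp_trace(spec)
        with pytest.warns(UserWarning):
            assert baseline_icp(trace, window=900.0) == pytest.approx(truth.baseline, abs=0.1)

    def test_all_masked_raises(self):
        trace = PressureTrace.from_samples(np.full(1000, np.nan), fs=100.0)
        with pytest.raises(UnusableTraceError):
            baseline_icp(trace, window=5.0)
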