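"""Filters, onset detection and outcome extraction against analytic oracles."""

import math

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from dynoreli import (
    OnsetSpec,
    SignalTrace,
    TraceParams,
    Units,
    bandpass_emg,
    compute_mvc,
    compute_peak_emg,
    compute_rfd200,
    compute_t90,
    detect_onset,
    emg_rms_envelope,
    extract_trial_outcomes,
    generate_trial_trace,
    lowpass_force,
)

RATE = 1961.0


def _trace(samples, units=Units.NEWTON, rate=RATE):
    return SignalTrace(np.asarray(samples, float), rate, units)


def _t(dur=6.0, rate=RATE):
    return np.arange(int(rate * dur)) / rate


class TestLowpassForce:
    def test_dc_passthrough(self):
        out = lowpass_force(_trace(np.full(int(RATE * 3), 7.5)))
        np.testing.assert_allclose(out.samples, 7.5, rtol=1e-9)

    def test_50hz_attenuated_by_squared_butterworth_response(self):
        # two filtfilt passes square the magnitude response:
        # (1 + (50/15)^8)^-1 ~ 6.7e-5, far below the 1e-3 bound
        t = _t()
        out = lowpass_force(_trace(np.sin(2 * np.pi * 50 * t)))
        mid = out.samples[len(t) // 4 : 3 * len(t) // 4]
        assert np.abs(mid).max() < 1e-3

    def test_zero_phase_preserves_peak_location(self):
        t = _t()
        tri = np.maximum(0.0, 1.0 - np.abs(t - 3.0) / 1.5)  # apex at t = 3 s
        out = lowpass_force(_trace(tri))
        apex = np.argmax(out.samples) / RATE
        assert abs(apex - 3.0) < 1.5 / RATE

    def test_rejects_low_rate(self):
        with pytest.raises(ValueError, match="30 Hz"):
            lowpass_force(_trace(np.zeros(100), rate=25.0))

    def test_rejects_too_short_trace(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass_force(_trace(np.zeros(40), rate=40.0))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, scale):
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1, int(RATE * 2))
        base = lowpass_force(_trace(x)).samples
        scaled = lowpass_force(_trace(scale * x)).samples
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-9, atol=1e-12 * scale)


class TestBandpassEmg:
    def test_out_of_band_2hz_rejected(self):
        t = _t()
        out = bandpass_emg(_trace(np.sin(2 * np.pi * 2 * t), Units.VOLT))
        mid = out.samples[len(t) // 4 : 3 * len(t) // 4]
        assert np.abs(mid).max() < 0.1

    def test_passband_100hz_preserved(self):
        t = _t()
        out = bandpass_emg(_trace(np.sin(2 * np.pi * 100 * t), Units.VOLT))
        mid = out.samples[len(t) // 4 : 3 * len(t) // 4]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        out = bandpass_emg(_trace(np.zeros(int(RATE * 2)), Units.VOLT))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_rejects_rate_at_or_below_1khz(self):
        with pytest.raises(ValueError, match="1000 Hz"):
            bandpass_emg(_trace(np.zeros(2000), Units.VOLT, rate=1000.0))


class TestDetectOnset:
    def test_noiseless_step_onset_exact(self):
        t = _t()
        x = np.where(t >= 1.0, 100.0, 0.0)
        res = detect_onset(_trace(x))
        assert res.onset_s == pytest.approx(round(1.0 * RATE) / RATE, abs=1e-12)
        assert res.baseline_sd == 0.0

    def test_threshold_is_mean_plus_k_sd(self):
        # baseline engineered to mean 1.0, SD 0.2 exactly (alternating +-0.2)
        n_base = int(round(0.5 * RATE))
        base = 1.0 + 0.2 * np.where(np.arange(n_base) % 2 == 0, 1.0, -1.0)
        x = np.concatenate([base, np.full(int(RATE * 2), 100.0)])
        res = detect_onset(_trace(x))
        sd = np.std(base, ddof=1)
        assert res.baseline_mean == pytest.approx(1.0)
        assert res.threshold == pytest.approx(1.0 + 3 * sd)

    def test_matches_brute_force_scan(self, rng):
        """Vectorised detector equals a sample-by-sample scan of the same rule."""
        spec = OnsetSpec()
        trial = generate_trial_trace(TraceParams(), rng, include_emg=False)
        filtered = lowpass_force(trial.force)
        res = detect_onset(filtered, spec)

        x = filtered.samples
        n_base = int(round(spec.baseline_window_s * RATE))
        thr = x[:n_base].mean() + spec.k_sd * x[:n_base].std(ddof=1)
        hold = int(round(spec.min_hold_s * RATE))
        brute = None
        for i in range(len(x) - hold + 1):
            if all(x[i + j] > thr for j in range(hold)):
                brute = i
                break
        assert brute is not None
        assert res.onset_index == brute
        assert abs(res.onset_s - brute / RATE) < 1e-12

    @given(k_lo=st.floats(1.0, 5.0), k_extra=st.floats(0.1, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_raising_k_sd_never_gives_earlier_onset(self, k_lo, k_extra):
        rng = np.random.default_rng(7)
        trial = generate_trial_trace(TraceParams(), rng, include_emg=False)
        filtered = lowpass_force(trial.force)
        lo = detect_onset(filtered, OnsetSpec(k_sd=k_lo))
        hi = detect_onset(filtered, OnsetSpec(k_sd=k_lo + k_extra))
        assert hi.onset_index >= lo.onset_index

    def test_no_onset_raises(self):
        rng = np.random.default_rng(0)
        flat = _trace(rng.normal(0, 1, int(RATE * 2)))
        with pytest.raises(ValueError, match="no onset"):
            detect_onset(flat, OnsetSpec(k_sd=50.0))

    def test_baseline_window_exceeding_trace_raises(self):
        with pytest.raises(ValueError, match="baseline window"):
            detect_onset(_trace(np.zeros(int(RATE))), OnsetSpec(baseline_window_s=2.0))


class TestMvcRfdT90:
    def test_mvc_is_peak_minus_baseline(self):
        t = _t()
        x = np.where(t >= 1.0, 102.0, 2.0)
        mvc, peak_time = compute_mvc(_trace(x), baseline_mean=2.0)
        assert mvc == pytest.approx(100.0)
        assert peak_time >= 1.0

    def test_mvc_matches_brute_force(self, rng):
        trial = generate_trial_trace(TraceParams(), rng, include_emg=False)
        res = detect_onset(trial.force)
        mvc, _ = compute_mvc(trial.force, res.baseline_mean)
        assert mvc == pytest.approx(trial.force.samples.max() - res.baseline_mean, abs=1e-12)

    @given(slope=st.floats(10.0, 5000.0))
    @settings(max_examples=30, deadline=None)
    def test_rfd_of_ramp_equals_slope(self, slope):
        t = _t(3.0)
        x = np.where(t >= 1.0, slope * (t - 1.0), 0.0)
        rfd = compute_rfd200(_trace(x), onset_s=1.0, baseline_mean=0.0)
        assert abs(rfd - slope) <= slope * (1.0 / RATE) / 0.2 + 1e-9

    def test_rfd_of_flat_trace_is_zero(self):
        rfd = compute_rfd200(_trace(np.full(int(RATE * 2), 5.0)), 0.5, 5.0)
        assert rfd == 0.0

    def test_rfd_requires_200ms_of_trace(self):
        with pytest.raises(ValueError, match="200 ms"):
            compute_rfd200(_trace(np.zeros(int(RATE))), onset_s=0.9, baseline_mean=0.0)

    def test_rfd_logistic_matches_closed_form(self):
        p = TraceParams(baseline_noise_sd=0.0)
        from dynoreli.synthetic import force_profile

        t = _t(p.onset_time + p.plateau_duration)
        x = force_profile(p, t)
        rfd = compute_rfd200(_trace(x), p.onset_time, 0.0)
        expected = p.peak_force * math.tanh(0.2 / (2 * p.rise_tau)) / 0.2
        assert rfd == pytest.approx(expected, abs=expected * (1 / RATE) / 0.2 + 1e-6)

    def test_t90_of_1s_ramp_is_0p9(self):
        t = _t()
        x = np.where(t >= 1.0, np.minimum(500.0 * (t - 1.0), 500.0), 0.0)
        mvc, _ = compute_mvc(_trace(x), 0.0)
        t90 = compute_t90(_trace(x), 1.0, 0.0, mvc)
        assert t90 == pytest.approx(0.9, abs=1.5 / RATE)

    def test_t90_of_step_is_zero(self):
        t = _t()
        x = np.where(t >= 1.0, 100.0, 0.0)
        t90 = compute_t90(_trace(x), round(1.0 * RATE) / RATE, 0.0, 100.0)
        assert t90 == 0.0

    def test_t90_logistic_matches_closed_form(self):
        p = TraceParams(baseline_noise_sd=0.0)
        from dynoreli.synthetic import force_profile

        t = _t(p.onset_time + p.plateau_duration)
        x = force_profile(p, t)
        mvc, _ = compute_mvc(_trace(x), 0.0)
        t90 = compute_t90(_trace(x), p.onset_time, 0.0, mvc)
        # mvc is the (finite-duration) trace max, slightly below the asymptote
        expected = 2 * p.rise_tau * math.atanh(0.9 * mvc / p.peak_force)
        assert t90 == pytest.approx(expected, abs=2 / RATE)

    @given(st.lists(st.floats(100.0, 3000.0), min_size=2, max_size=5, unique=True))
    @settings(max_examples=20, deadline=None)
    def test_t90_non_increasing_with_steeper_ramps(self, slopes):
        t = _t(4.0)
        t90s = []
        for slope in sorted(slopes):
            x = np.where(t >= 1.0, np.minimum(slope * (t - 1.0), 500.0), 0.0)
            mvc, _ = compute_mvc(_trace(x), 0.0)
            t90s.append(compute_t90(_trace(x), 1.0, 0.0, mvc))
        assert all(a >= b - 1e-12 for a, b in zip(t90s, t90s[1:]))


class TestEmg:
    def test_envelope_of_sinusoid_is_amplitude_over_sqrt2(self):
        t = _t()
        env = emg_rms_envelope(_trace(0.3 * np.sin(2 * np.pi * 100 * t), Units.VOLT), 0.05)
        mid = env.samples[500:-500]
        np.testing.assert_allclose(mid, 0.3 / math.sqrt(2), rtol=0.01)

    def test_envelope_of_zero_is_zero(self):
        env = emg_rms_envelope(_trace(np.zeros(int(RATE * 2)), Units.VOLT), 0.05)
        assert np.all(env.samples == 0.0)

    def test_envelope_of_white_noise_estimates_sigma(self):
        rng = np.random.default_rng(3)
        env = emg_rms_envelope(_trace(rng.normal(0, 0.2, int(RATE * 6)), Units.VOLT), 0.05)
        assert env.samples.mean() == pytest.approx(0.2, rel=0.05)

    def test_envelope_window_longer_than_trace_raises(self):
        with pytest.raises(ValueError, match="longer than the trace"):
            emg_rms_envelope(_trace(np.zeros(int(RATE)), Units.VOLT), 2.0)

    def test_peak_emg_constant_envelope(self):
        env = _trace(np.full(int(RATE * 4), 0.2), Units.VOLT)
        assert compute_peak_emg(env, 2.0) == pytest.approx(0.2)

    def test_peak_emg_bump_inside_window(self):
        t = _t(4.0)
        env = _trace(np.maximum(0.0, 0.5 - np.abs(t - 2.3)), Units.VOLT)
        assert compute_peak_emg(env, 2.0) == pytest.approx(0.5, abs=1e-3)

    def test_peak_emg_equals_brute_force_over_clipped_range(self, rng):
        trial = generate_trial_trace(TraceParams(), rng)
        env = emg_rms_envelope(bandpass_emg(trial.emg), 0.05)
        _, peak_time = compute_mvc(lowpass_force(trial.force), 0.0)
        got = compute_peak_emg(env, peak_time)
        lo = max(0, int(np.ceil((peak_time - 1.0) * RATE)))
        hi = min(env.n_samples - 1, int(np.floor((peak_time + 1.0) * RATE)))
        assert got == max(env.samples[i] for i in range(lo, hi + 1))

    def test_window_outside_recording_raises(self):
        env = _trace(np.full(int(RATE * 2), 0.1), Units.VOLT)
        with pytest.raises(ValueError, match="window"):
            compute_peak_emg(env, 100.0)


class TestExtractTrialOutcomes:
    def test_deterministic_for_fixed_seed(self, default_trace_params):
        a = extract_trial_outcomes(
            generate_trial_trace(default_trace_params, np.random.default_rng(5))
        )
        b = extract_trial_outcomes(
            generate_trial_trace(default_trace_params, np.random.default_rng(5))
        )
        assert a == b

    def test_emg_absent_propagates(self, default_trace_params, rng):
        trial = generate_trial_trace(default_trace_params, rng, include_emg=False)
        out = extract_trial_outcomes(trial)
        assert out.peak_emg_rms_v is None

    def test_matches_straight_line_reimplementation(self):
        """20 seeded trials: the pipeline equals an independent flat rewrite
        of the processing rules (filter, 3-SD onset with hold, MVC, RFD200,
        t90, EMG RMS peak)."""
        spec = OnsetSpec()
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            trial = generate_trial_trace(TraceParams(), rng)
            got = extract_trial_outcomes(trial, spec)

            # ---- independent straight-line version ----
            rate = trial.force.rate_hz
            sos = scipy.signal.butter(4, 15, "lowpass", fs=rate, output="sos")
            f = scipy.signal.sosfiltfilt(sos, trial.force.samples)
            nb = int(round(0.5 * rate))
            m, s = f[:nb].mean(), f[:nb].std(ddof=1)
            thr = m + 3 * s
            hold = int(round(0.025 * rate))
            onset_i = next(
                i for i in range(len(f) - hold + 1) if np.all(f[i : i + hold] > thr)
            )
            mvc = f.max() - m
            peak_i = int(np.argmax(f))
            rfd = (f[int(round(onset_i + 0.2 * rate))] - m) / 0.2
            t90_i = next(i for i in range(onset_i, len(f)) if f[i] - m >= 0.9 * mvc)
            t90 = (t90_i - onset_i) / rate
            sos_e = scipy.signal.butter(4, (10, 500), "bandpass", fs=rate, output="sos")
            e = scipy.signal.sosfiltfilt(sos_e, trial.emg.samples)
            w = int(round(0.05 * rate))
            e2 = np.convolve(e**2, np.ones(w), "same")
            cnt = np.convolve(np.ones_like(e), np.ones(w), "same")
            env = np.sqrt(e2 / cnt)
            lo = max(0, int(np.ceil((peak_i / rate - 1.0) * rate)))
            hi = min(len(env) - 1, int(np.floor((peak_i / rate + 1.0) * rate)))
            peak_emg = env[lo : hi + 1].max()

            assert got.onset_s == pytest.approx(onset_i / rate, abs=1e-12)
            assert got.mvc_n == pytest.approx(mvc, rel=1e-12)
            assert got.rfd200_n_per_s == pytest.approx(rfd, rel=1e-12)
            assert got.t90_s == pytest.approx(t90, abs=1e-12)
            assert got.peak_emg_rms_v == pytest.approx(peak_emg, rel=1e-9)
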