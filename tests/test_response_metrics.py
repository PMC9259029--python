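import math

import numpy as np
import pytest

from gazestab import (
    AnalysisConfig,
    PolarResponse,
    PsdConfig,
    ResponseModel,
    StimulusSpec,
    Trial,
    TrialMeta,
    UndefinedPhaseError,
    amplitude_at,
    analyze_trial,
    compensation_error,
    compute_gain,
    generate_response,
    generate_stimulus,
    msc_coherence,
    phase_fft,
    phase_xcorr,
    polar_distance,
)
from gazestab.preprocess import AnalysisWindow, exclude_ramps

FS = 1200.0


def whole_cycle_window(f, n_cycles, fs=FS):
    return AnalysisWindow(0, int(round(n_cycles * fs / f)))


def circ_diff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestAmplitudeAt:
    def test_pure_tone(self):
        w = whole_cycle_window(2.0, 7)
        t = np.arange(w.length) / FS
        x = 30.0 * np.sin(2 * np.pi * 2.0 * t)
        assert amplitude_at(x, 2.0, FS, w) == pytest.approx(30.0, rel=1e-9)

    def test_orthogonal_component_ignored(self):
        w = whole_cycle_window(2.0, 7)
        t = np.arange(w.length) / FS
        x = 30.0 * np.sin(2 * np.pi * 2.0 * t) + 5.0 * np.sin(2 * np.pi * 12.0 * t)
        assert amplitude_at(x, 2.0, FS, w) == pytest.approx(30.0, rel=1e-9)
        assert amplitude_at(x, 12.0, FS, w) == pytest.approx(5.0, rel=1e-9)

    def test_noise_floor_monte_carlo(self):
        # DFT amplitude of N(0,1) noise at one bin: Rayleigh with
        # sigma = sd * sqrt(2/N) -> mean well below 0.1 deg for N = 4200
        w = whole_cycle_window(2.0, 7)
        amps = []
        for seed in range(30):
            x = np.random.default_rng(seed).normal(0.0, 1.0, w.length)
            amps.append(amplitude_at(x, 2.0, FS, w))
        expected_mean = math.sqrt(math.pi / 2) * math.sqrt(2.0 / w.length)
        assert np.mean(amps) == pytest.approx(expected_mean, rel=0.5)
        assert np.mean(amps) < 0.1

    def test_off_grid_frequency_rejected(self):
        w = AnalysisWindow(0, 4100)  # not a whole number of 2 Hz cycles
        with pytest.raises(ValueError, match="grid"):
            amplitude_at(np.zeros(4100), 2.0, FS, w)

    def test_window_shorter_than_one_cycle_rejected(self):
        w = AnalysisWindow(0, 300)
        with pytest.raises(ValueError, match="one cycle"):
            amplitude_at(np.ones(300), 2.0, FS, w)


class TestComputeGain:
    def test_ideal_compensation(self, spec2, stim2, ideal_trial):
        window = exclude_ramps(ideal_trial, spec2)
        g = compute_gain(stim2, ideal_trial.theta_head_thorax, 2.0, FS, window)
        assert g == pytest.approx(1.0, rel=1e-9)

    def test_scaled_shifted_response(self):
        w = whole_cycle_window(2.0, 7)
        t = np.arange(w.length) / FS
        stim = 30.0 * np.sin(2 * np.pi * 2.0 * t)
        resp = 0.5 * 30.0 * np.sin(2 * np.pi * 2.0 * t + 1.234)
        assert compute_gain(stim, resp, 2.0, FS, w) == pytest.approx(0.5, rel=1e-9)

    def test_noise_only_response_near_zero(self):
        w = whole_cycle_window(2.0, 7)
        t = np.arange(w.length) / FS
        stim = 30.0 * np.sin(2 * np.pi * 2.0 * t)
        resp = np.random.default_rng(0).normal(0.0, 0.5, w.length)
        assert compute_gain(stim, resp, 2.0, FS, w) < 0.01

    def test_missing_stimulus_rejected(self):
        w = whole_cycle_window(2.0, 7)
        flat = np.zeros(w.length)
        with pytest.raises(ValueError, match="floor"):
            compute_gain(flat, flat, 2.0, FS, w)


class TestPhaseEstimators:
    def setup_pair(self, psi_deg, f=2.0, n_cycles=7):
        w = whole_cycle_window(f, n_cycles)
        t = np.arange(w.length) / FS
        stim = 30.0 * np.sin(2 * np.pi * f * t)
        resp = 18.0 * np.sin(2 * np.pi * f * t + np.radians(psi_deg))
        return stim, resp, w

    @pytest.mark.parametrize("psi", [0.0, 90.0, 177.6, 180.0, 270.0, 302.4])
    def test_both_estimators_recover_generative_phase(self, psi):
        stim, resp, w = self.setup_pair(psi)
        assert circ_diff(phase_xcorr(stim, resp, 2.0, FS, w), psi) <= 0.5
        assert phase_fft(stim, resp, 2.0, FS, w) == pytest.approx(psi % 360.0, abs=1e-6)

    def test_antiphase_is_180(self):
        stim, _, w = self.setup_pair(0.0)
        assert phase_xcorr(stim, -stim, 2.0, FS, w) == pytest.approx(180.0)
        assert phase_fft(stim, -stim, 2.0, FS, w) == pytest.approx(180.0)

    def test_identity_is_0(self):
        stim, _, w = self.setup_pair(0.0)
        assert phase_xcorr(stim, stim, 2.0, FS, w) == pytest.approx(0.0)
        assert phase_fft(stim, stim, 2.0, FS, w) == pytest.approx(0.0)

    def test_quarter_period_shift(self):
        # response leading by 1/(4f) has phase 90; a lagging one has 270
        stim, resp, w = self.setup_pair(90.0)
        lag_res = 360.0 * 2.0 / FS
        assert circ_diff(phase_xcorr(stim, resp, 2.0, FS, w), 90.0) <= lag_res
        assert phase_fft(stim, resp, 2.0, FS, w) == pytest.approx(90.0, abs=1e-6)
        stim, resp, w = self.setup_pair(-90.0)
        assert circ_diff(phase_xcorr(stim, resp, 2.0, FS, w), 270.0) <= lag_res

    def test_flat_series_raises_sentinel(self):
        stim, _, w = self.setup_pair(0.0)
        flat = np.zeros(w.length)
        with pytest.raises(UndefinedPhaseError):
            phase_xcorr(stim, flat, 2.0, FS, w)
        with pytest.raises(UndefinedPhaseError):
            phase_fft(stim, flat, 2.0, FS, w)

    def test_estimator_agreement_under_default_noise(self, spec2, stim2):
        # mirrors the published cross-check: the two methods nearly coincide
        agree = 0
        for seed in range(100):
            model = ResponseModel(gain=0.6, phase=177.6, seed=seed)
            trial = generate_response(stim2, model, spec2)
            m = analyze_trial(trial, spec2)
            if circ_diff(m.phase_fft, m.phase_xcorr) <= 5.0:
                agree += 1
        assert agree >= 95


class TestPolarDistanceAndEpsilon:
    def test_identity_distance_zero(self):
        p = PolarResponse(0.7, 123.0)
        assert polar_distance(p, p) == 0.0

    def test_antipodal_unit_points(self):
        assert polar_distance(PolarResponse(1, 0), PolarResponse(1, 180)) == pytest.approx(2.0)

    def test_law_of_cosines_by_hand(self):
        # d^2 = 1 + 0.25 - 2*0.5*cos(90 deg) = 1.25
        d = polar_distance(PolarResponse(1.0, 180.0), PolarResponse(0.5, 90.0))
        assert d == pytest.approx(math.sqrt(1.25), rel=1e-12)

    @pytest.mark.parametrize(
        "r,theta,expected",
        [(1.0, 180.0, 0.0), (1.0, 0.0, 2.0), (0.0, 0.0, 1.0), (0.0, 77.0, 1.0)],
    )
    def test_epsilon_anchors(self, r, theta, expected):
        assert compensation_error(PolarResponse(r, theta)) == pytest.approx(expected, abs=1e-12)

    def test_epsilon_equals_distance_to_perfect_point(self):
        rng = np.random.default_rng(1)
        perfect = PolarResponse(1.0, 180.0)
        for _ in range(200):
            p = PolarResponse(rng.uniform(0, 1.5), rng.uniform(0, 360))
            assert compensation_error(p) == pytest.approx(
                polar_distance(p, perfect), abs=1e-12
            )


class TestCoherence:
    def test_noise_free_linear_response(self, spec2, stim2, ideal_trial):
        window = exclude_ramps(ideal_trial, spec2)
        c = msc_coherence(stim2, 0.7 * stim2 + 3.0, 2.0, FS, window)
        assert c >= 0.99

    def test_independent_noise_low(self, spec2, stim2, ideal_trial):
        window = exclude_ramps(ideal_trial, spec2)
        values = [
            msc_coherence(
                stim2,
                np.random.default_rng(seed).normal(0, 1, spec2.n_samples),
                2.0, FS, window,
            )
            for seed in range(50)
        ]
        assert np.mean(values) <= 0.2

    def test_monotone_in_noise(self, spec2, stim2):
        means = []
        for noise_sd in (0.5, 2.0, 8.0, 32.0):
            vals = []
            for seed in range(20):
                model = ResponseModel(gain=0.6, phase=177.6, wingbeat_amp=0.0,
                                      wobble_amp=0.0, noise_sd=noise_sd, seed=seed)
                trial = generate_response(stim2, model, spec2)
                window = exclude_ramps(trial, spec2)
                vals.append(msc_coherence(stim2, trial.theta_head_thorax, 2.0, FS, window))
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_single_segment_rejected(self):
        spec = StimulusSpec(2.0, 30.0, 2, FS, ramp_endpoints=False)
        stim = generate_stimulus(spec)
        w = AnalysisWindow(0, spec.period_samples)  # one cycle = one segment
        with pytest.raises(ValueError, match="psd_config"):
            msc_coherence(stim, -stim, 2.0, FS, w)


class TestAnalyzeTrial:
    def test_ideal_trial(self, spec2, ideal_trial):
        m = analyze_trial(ideal_trial, spec2)
        assert m.gain == pytest.approx(1.0, rel=1e-6)
        assert m.phase_xcorr == pytest.approx(180.0, abs=0.5)
        assert m.epsilon == pytest.approx(0.0, abs=0.01)
        assert m.coherence >= 0.99
        assert m.flags == ()

    def test_noisy_generative_recovery(self, spec2, stim2):
        model = ResponseModel(gain=0.6, phase=177.6, seed=5)
        trial = generate_response(stim2, model, spec2)
        m = analyze_trial(trial, spec2)
        assert m.gain == pytest.approx(0.6, abs=0.02)
        assert circ_diff(m.phase_xcorr, 177.6) <= 3.0
        assert circ_diff(m.phase_fft, 177.6) <= 3.0

    def test_zero_response_trial(self, spec2, stim2):
        t = np.arange(spec2.n_samples) / FS
        trial = Trial(t, stim2, np.zeros(spec2.n_samples), TrialMeta(2.0, 30.0))
        m = analyze_trial(trial, spec2)
        assert m.gain == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(m.phase_xcorr) and math.isnan(m.phase_fft)
        assert m.epsilon == pytest.approx(1.0)
        assert "phase_undefined" in m.flags

    def test_epsilon_uses_configured_estimator(self, spec2, noisy_trial):
        m_x = analyze_trial(noisy_trial, spec2, AnalysisConfig(epsilon_phase="xcorr"))
        m_f = analyze_trial(noisy_trial, spec2, AnalysisConfig(epsilon_phase="fft"))
        eps_fft = compensation_error(PolarResponse(m_f.gain, m_f.phase_fft))
        assert m_f.epsilon == pytest.approx(eps_fft, abs=1e-12)
        assert m_x.epsilon == pytest.approx(
            compensation_error(PolarResponse(m_x.gain, m_x.phase_xcorr)), abs=1e-12
        )

    def test_gain_scale_invariance(self, spec2, noisy_trial):
        m1 = analyze_trial(noisy_trial, spec2)
        scaled = Trial(
            noisy_trial.time,
            3.7 * noisy_trial.theta_thorax,
            3.7 * noisy_trial.theta_head_thorax,
            noisy_trial.meta,
        )
        m2 = analyze_trial(scaled, spec2)
        assert m2.gain == pytest.approx(m1.gain, rel=1e-9)
        assert m2.phase_xcorr == pytest.approx(m1.phase_xcorr, abs=1e-9)
        assert m2.phase_fft == pytest.approx(m1.phase_fft, abs=1e-9)
        assert m2.epsilon == pytest.approx(m1.epsilon, rel=1e-9)
        assert m2.coherence == pytest.approx(m1.coherence, rel=1e-9)

    def test_filter_phase_neutral_at_stimulus_frequency(self, spec2, stim2):
        model = ResponseModel(gain=0.6, phase=177.6, wingbeat_amp=0.0,
                              wobble_amp=0.0, noise_sd=0.0)
        trial = generate_response(stim2, model, spec2)
        window = exclude_ramps(trial, spec2)
        raw = phase_fft(stim2, trial.theta_head_thorax, 2.0, FS, window)
        filtered = analyze_trial(trial, spec2).phase_fft
        assert circ_diff(raw, filtered) <= 0.5

    def test_stage_identity_in_errors(self, spec2):
        spec_short = StimulusSpec(2.0, 30.0, 1, FS, ramp_endpoints=True)
        theta = generate_stimulus(spec_short)
        t = np.arange(spec_short.n_samples) / FS
        trial = Trial(t, theta, -theta, TrialMeta(2.0, 30.0))
        with pytest.raises(ValueError, match="exclude_ramps"):
            analyze_trial(trial, spec_short)

    def test_parameter_recovery_grid(self, spec2, stim2):
        # cohort-scale recovery over the generative grid, 10 seeds per cell
        for gain in (0.1, 0.4, 0.6, 1.0):
            for phase in (0.0, 90.0, 177.6, 302.4):
                gains, phases = [], []
                for seed in range(10):
                    model = ResponseModel(gain=gain, phase=phase, seed=seed)
                    m = analyze_trial(generate_response(stim2, model, spec2), spec2)
                    gains.append(m.gain)
                    phases.append(m.phase_xcorr)
                assert abs(np.median(gains) - gain) <= 0.02
                med = np.median([(p - phase + 180.0) % 360.0 - 180.0 for p in phases])
                assert abs(med) <= 3.0
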