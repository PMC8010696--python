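"""Sweep-VEP chain: grid, filtering, epoching, RLS, averaging, thresholds."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from meridianvision import (EEGTrial, NoiseConfig, SweepStimulus,
                            SweepVEPAnalyzer, analysis_bandpass,
                            coherent_average, epoch_trial,
                            estimate_svep_threshold, generate_sweep_trial,
                            noise_and_snr, occipital_average,
                            rls_coefficients, sweep_frequencies)
from meridianvision.sweep_vep import SweepResponse

FS = 2048.0


def pure_tone_trial(freq, amplitude=3.0, stimulus=None, phase=0.0):
    stimulus = stimulus or SweepStimulus()
    n = int(FS * stimulus.duration)
    t = np.arange(n) / FS
    wave = amplitude * np.cos(2 * np.pi * freq * t + phase)
    return EEGTrial(samples=np.tile(wave, (3, 1)),
                    channel_names=("Oz", "O1", "O2"), sampling_rate=FS,
                    stimulus=stimulus, meridian="strong")


def dft_amplitude(x, freq, fs=FS):
    t = np.arange(x.size) / fs
    return abs(2.0 / x.size * np.sum(x * np.exp(-2j * np.pi * freq * t)))


class TestSweepGrid:
    def test_endpoints(self):
        sfs = sweep_frequencies(2, 16, 10)
        assert sfs[0] == 2.0 and sfs[-1] == 16.0

    def test_fifth_step(self):
        assert round(sweep_frequencies(2, 16, 10)[4], 1) == 8.2

    def test_all_rounded_labels(self):
        labels = [round(f, 1) for f in sweep_frequencies(2, 16, 10)]
        assert labels == [2.0, 3.6, 5.1, 6.7, 8.2, 9.8, 11.3, 12.9, 14.4, 16.0]

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            sweep_frequencies(2, 16, 1)
        with pytest.raises(ValueError):
            sweep_frequencies(16, 2, 10)


class TestBandpass:
    def test_passband_identity_at_12hz(self):
        filtered = analysis_bandpass(pure_tone_trial(12.0))
        amp = dft_amplitude(filtered.channel("Oz"), 12.0)
        assert amp == pytest.approx(3.0, rel=0.01)

    def test_50hz_attenuated(self):
        filtered = analysis_bandpass(pure_tone_trial(50.0))
        amp = dft_amplitude(filtered.channel("Oz"), 50.0)
        assert 20 * math.log10(amp / 3.0) <= -20.0

    def test_dc_removed(self):
        stim = SweepStimulus()
        n = int(FS * stim.duration)
        trial = EEGTrial(samples=np.full((3, n), 5.0),
                         channel_names=("Oz", "O1", "O2"), sampling_rate=FS,
                         stimulus=stim, meridian="strong")
        filtered = analysis_bandpass(trial)
        # interior mean, away from the zero-phase filter's edge transients
        dc = abs(np.mean(filtered.channel("Oz")[n // 4: 3 * n // 4]))
        assert 20 * math.log10(max(dc, 1e-12) / 5.0) <= -40.0

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            analysis_bandpass(pure_tone_trial(12.0), low=1.0, high=2000.0)


class TestEpoching:
    def test_partition_shape_and_identity(self, observer, stimulus, silent_noise):
        trial = generate_sweep_trial(observer, stimulus, "strong",
                                     silent_noise, 3)
        sfs, epochs = epoch_trial(trial)
        assert epochs.shape == (10, 3, 2048)
        np.testing.assert_array_equal(sfs, stimulus.step_frequencies)
        rebuilt = np.concatenate([epochs[k] for k in range(10)], axis=1)
        np.testing.assert_array_equal(rebuilt, trial.samples)

    def test_length_mismatch_raises(self, observer, silent_noise):
        trial = generate_sweep_trial(observer, SweepStimulus(), "strong",
                                     silent_noise, 3, sampling_rate=100.0)
        with pytest.raises(ValueError):
            epoch_trial(_IndivisibleTrial(trial))


class _IndivisibleTrial:
    """Duck-typed trial whose sample count is indivisible by n_steps."""

    def __init__(self, trial):
        self.stimulus = SweepStimulus(duration=10.0, n_steps=7)
        self.samples = trial.samples
        self.channel_names = trial.channel_names
        self.sampling_rate = trial.sampling_rate
        self.n_samples = trial.samples.shape[1]


class TestRLS:
    def test_noiseless_amplitude_recovery(self):
        t = np.arange(2048) / FS
        y = 3.0 * np.cos(2 * np.pi * 12.0 * t + 0.7)
        coeffs = rls_coefficients(y, [11.0, 12.0, 13.0], FS)
        assert abs(coeffs[12.0]) == pytest.approx(3.0, abs=1e-6)
        assert abs(coeffs[11.0]) == pytest.approx(0.0, abs=1e-6)

    def test_phase_equivariance(self):
        t = np.arange(2048) / FS
        base = rls_coefficients(2.0 * np.cos(2 * np.pi * 12.0 * t),
                                [12.0], FS)[12.0]
        shifted = rls_coefficients(2.0 * np.cos(2 * np.pi * 12.0 * t + 1.1),
                                   [12.0], FS)[12.0]
        assert abs(shifted) == pytest.approx(abs(base), abs=1e-6)
        delta = np.angle(shifted) - np.angle(base)
        assert (delta + np.pi) % (2 * np.pi) - np.pi == pytest.approx(1.1, abs=1e-6)

    def test_zero_content_gives_zero(self):
        t = np.arange(2048) / FS
        y = 1.0 * np.cos(2 * np.pi * 7.0 * t)  # orthogonal bin
        assert abs(rls_coefficients(y, [12.0], FS)[12.0]) < 1e-9

    def test_matches_least_squares_oracle(self, rng):
        # lambda = 1 equals the closed-form projection, 100 random epochs
        targets = [11.0, 12.0, 13.0]
        n = 2048
        t = np.arange(n) / FS
        X = np.column_stack(sum((([np.cos(2 * np.pi * f * t),
                                   np.sin(2 * np.pi * f * t)]) for f in targets),
                                []))
        for _ in range(100):
            y = rng.standard_normal(n)
            theta = np.linalg.lstsq(X, y, rcond=None)[0]
            oracle = {f: complex(theta[2 * j], -theta[2 * j + 1])
                      for j, f in enumerate(targets)}
            ours = rls_coefficients(y, targets, FS, forgetting_factor=1.0)
            for f in targets:
                assert abs(ours[f] - oracle[f]) <= 1e-6 * max(1.0, abs(oracle[f]))

    def test_integer_cycle_epochs_match_dft_bin(self, rng):
        y = rng.standard_normal(2048)
        ours = rls_coefficients(y, [12.0], FS)[12.0]
        t = np.arange(2048) / FS
        dft = 2.0 / 2048 * np.sum(y * np.exp(-2j * np.pi * 12.0 * t))
        assert abs(abs(ours) - abs(dft)) < 1e-9

    def test_forgetting_factor_tracks_recent_signal(self):
        # amplitude steps mid-epoch; exponential forgetting favours the end
        t = np.arange(4096) / FS
        y = np.where(t < 1.0, 1.0, 5.0) * np.cos(2 * np.pi * 12.0 * t)
        full = abs(rls_coefficients(y, [12.0], FS, 1.0)[12.0])
        recent = abs(rls_coefficients(y, [12.0], FS, 0.995)[12.0])
        assert recent > full
        assert recent == pytest.approx(5.0, rel=0.05)

    def test_validation(self):
        y = np.zeros(100)
        with pytest.raises(ValueError):
            rls_coefficients(y, [12.0, 12.0], FS)
        with pytest.raises(ValueError):
            rls_coefficients(y, [2000.0], FS)
        with pytest.raises(ValueError):
            rls_coefficients(y, [12.0], FS, forgetting_factor=0.85)


class TestAveraging:
    def test_occipital_identity_and_cases(self):
        same = {c: {12.0: 1 + 2j} for c in ("Oz", "O1", "O2")}
        assert occipital_average(same)[12.0] == 1 + 2j
        cancel = {"Oz": {12.0: 1 + 0j}, "O1": {12.0: -1 + 0j},
                  "O2": {12.0: 0j}}
        assert occipital_average(cancel)[12.0] == 0j
        mix = {"Oz": {12.0: 1 + 0j}, "O1": {12.0: 1j}, "O2": {12.0: 0j}}
        assert occipital_average(mix)[12.0] == pytest.approx(1 / 3 + 1j / 3)

    def test_missing_channel_raises(self):
        with pytest.raises(ValueError):
            occipital_average({"Oz": {12.0: 1j}, "O1": {12.0: 1j}})

    def test_identical_trials_zero_se(self):
        z = np.tile(np.array([1 + 1j, 2 + 0j, 0 + 3j]), (5, 1))
        mean, se = coherent_average(z)
        np.testing.assert_allclose(mean, z[0])
        np.testing.assert_allclose(se, 0.0, atol=1e-12)

    def test_random_phase_vector_mean_vanishes(self, rng):
        n = 1000
        z = np.exp(2j * np.pi * rng.random((n, 1)))
        mean, _ = coherent_average(z)
        assert abs(mean[0]) < 4.0 / math.sqrt(n)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            coherent_average(np.array([[1 + 1j, 2 + 2j]]))

    def test_coherent_gain_grows_as_sqrt_n(self, rng):
        signal = 2.0 + 0j
        snrs = []
        for n in (4, 16, 64):
            ratios = []
            for _ in range(300):
                noise = (rng.standard_normal((n, 1))
                         + 1j * rng.standard_normal((n, 1)))
                mean, _ = coherent_average(signal + noise)
                ratios.append(abs(mean[0]))
            # residual noise scales ~ 1/sqrt(n)
            snrs.append(abs(signal) / np.std(np.array(ratios) - abs(signal)))
        assert snrs[1] / snrs[0] == pytest.approx(2.0, rel=0.35)
        assert snrs[2] / snrs[1] == pytest.approx(2.0, rel=0.35)


class TestSNR:
    def test_definition_arithmetic(self):
        noise, snr = noise_and_snr(np.array([6.0]),
                                   {11.0: np.array([1.0 + 0j]),
                                    13.0: np.array([3.0 + 0j])})
        assert noise[0] == 2.0
        assert snr[0] == 3.0

    def test_zero_noise_infinite_sentinel(self):
        _, snr = noise_and_snr(np.array([1.0]), {11.0: np.array([0j]),
                                                 13.0: np.array([0j])})
        assert np.isinf(snr[0])

    def test_pure_noise_snr_near_unity(self, rng):
        # equal-variance complex Gaussians in signal and noise bins
        ratios = []
        for _ in range(500):
            draws = (rng.standard_normal(3) + 1j * rng.standard_normal(3))
            _, snr = noise_and_snr(np.array([abs(draws[0])]),
                                   {11.0: np.array([draws[1]]),
                                    13.0: np.array([draws[2]])})
            ratios.append(snr[0])
        assert 0.7 < np.median(ratios) < 1.5


def make_response(sfs, amplitudes, snr):
    amplitudes = np.asarray(amplitudes, float)
    return SweepResponse(sfs=np.asarray(sfs, float),
                         vector_mean=amplitudes.astype(complex),
                         vector_se=np.zeros_like(amplitudes),
                         noise_amplitude=np.ones_like(amplitudes),
                         snr=np.asarray(snr, float), n_trials=10)


class TestThresholdRegression:
    def test_line_through_its_own_root(self):
        # linear descent to zero inside the sweep; the silent tail epochs
        # fail the SNR gate, so the window is the responsive limb and the
        # fitted line passes through its own root
        sfs = sweep_frequencies()
        amps = np.maximum(0.4 * (14.5 - sfs), 0.0)
        snr = np.where(amps > 0, 9.9, 0.5)
        fit = estimate_svep_threshold(make_response(sfs, amps, snr))
        assert fit.valid
        assert fit.intercept_sf == pytest.approx(14.5, abs=1e-9)

    def test_extrapolates_beyond_sweep_end(self):
        sfs = sweep_frequencies()
        amps = 0.3 * (19.0 - sfs)
        fit = estimate_svep_threshold(make_response(sfs, amps, np.full(10, 9.9)))
        assert fit.valid
        assert fit.intercept_sf == pytest.approx(19.0, abs=1e-9)
        assert fit.slope == pytest.approx(-0.3, abs=1e-12)

    def test_no_signal_window(self):
        sfs = sweep_frequencies()
        fit = estimate_svep_threshold(make_response(sfs, np.ones(10),
                                                    np.full(10, 1.0)))
        assert not fit.valid
        assert fit.reason == "no-signal-window"

    def test_short_window_invalid(self):
        sfs = sweep_frequencies()
        snr = np.full(10, 0.5)
        snr[-2:] = 9.0
        amps = np.linspace(5, 1, 10)
        fit = estimate_svep_threshold(make_response(sfs, amps, snr))
        assert not fit.valid
        assert fit.reason == "window-too-short"

    def test_flat_amplitudes_invalid_slope(self):
        sfs = sweep_frequencies()
        fit = estimate_svep_threshold(make_response(sfs, np.ones(10),
                                                    np.full(10, 9.0)))
        assert not fit.valid
        assert fit.reason == "non-negative-slope"

    def test_rising_amplitudes_leave_short_window(self):
        # a monotonically rising profile peaks at the last epoch, so the
        # scoring window collapses below the 3-epoch minimum
        sfs = sweep_frequencies()
        fit = estimate_svep_threshold(make_response(sfs, np.linspace(1, 5, 10),
                                                    np.full(10, 9.0)))
        assert not fit.valid
        assert fit.reason == "window-too-short"


class TestAnalyzer:
    def test_signal_frequency_is_second_harmonic(self):
        assert SweepVEPAnalyzer(temporal_freq=6.0, harmonic=2).signal_freq == 12.0

    def test_noiseless_exact_threshold_recovery(self, observer, stimulus,
                                                silent_noise):
        trials = [generate_sweep_trial(observer, stimulus, "strong",
                                       silent_noise, seed)
                  for seed in (1, 2)]
        an = SweepVEPAnalyzer(band=None).fit(trials)
        assert an.valid_
        assert an.threshold_ == pytest.approx(observer.vep_threshold_strong,
                                              abs=1e-6)
        expected = [observer.vep_peak_amplitude
                    * (observer.vep_threshold_strong - f)
                    / (observer.vep_threshold_strong - 2.0)
                    for f in stimulus.step_frequencies]
        np.testing.assert_allclose(an.amplitudes_, expected, atol=1e-9)
        # noise bins hold only numerical residue
        assert np.all(an.snr_ > 1e6)

    def test_default_noise_recovery_and_structure(self, observer, stimulus, rng):
        trials = [generate_sweep_trial(observer, stimulus, "weak",
                                       NoiseConfig(), rng) for _ in range(10)]
        an = SweepVEPAnalyzer().fit(trials)
        assert an.response_.n_trials == 10
        assert an.sweep_sfs_.shape == (10,)
        # vector-mean amplitude cannot exceed the mean of per-trial moduli
        assert an.valid_
        assert an.threshold_ == pytest.approx(observer.vep_threshold_weak,
                                              abs=2.0)

    def test_mismatched_trials_raise(self, observer, stimulus, silent_noise):
        t1 = generate_sweep_trial(observer, stimulus, "strong", silent_noise, 1)
        t2 = generate_sweep_trial(observer, SweepStimulus(duration=5.0),
                                  "strong", silent_noise, 2)
        with pytest.raises(ValueError):
            SweepVEPAnalyzer().fit([t1, t2])
        with pytest.raises(ValueError):
            SweepVEPAnalyzer().fit([t1])

    def test_sklearn_protocol(self):
        an = SweepVEPAnalyzer(criterion_snr=4.0)
        assert clone(an).get_params()["criterion_snr"] == 4.0
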