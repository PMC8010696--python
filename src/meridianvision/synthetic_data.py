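"""Synthetic observers and stimulus-locked EEG for meridian-specific spatial vision.

This module provides the generative side of the package: a truncated
log-parabola contrast sensitivity function (CSF) per meridian, a stochastic
Weibull observer for the two-interval forced-choice (2IFC) detection task,
and a sweep-VEP EEG generator that embeds a second-harmonic (12 Hz for a
6 Hz phase-reversing grating) response in 1/f-plus-white background noise.

Everything downstream (staircases, CSF summaries, sweep-VEP analysis,
group statistics) is testable against the generative truth held here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

Meridian = Literal["strong", "weak"]

#: quadratic coefficient of the log-parabola CSF (log10 sensitivity loss of
#: log10(2) when log10(f / peak_sf) equals half the bandwidth parameter)
_LOG_PARABOLA_K = 4.0 * math.log10(2.0)

OCCIPITAL_CHANNELS = ("Oz", "O1", "O2")


# ---------------------------------------------------------------------------
# generative CSF and observer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueCSF:
    """Truncated log-parabola contrast sensitivity function.

    log10 S(f) = log10(peak_gain)
                 - 4 log10(2) * (log10(f / peak_sf) / log_bandwidth)^2,
    with the low-frequency side floored at ``low_freq_truncation * peak_gain``.

    Parameters
    ----------
    peak_gain : float
        Sensitivity (1 / contrast threshold) at the peak, dimensionless, > 1.
    peak_sf : float
        Spatial frequency of the peak, cycles/degree.
    log_bandwidth : float
        Width parameter in log10-frequency units; sensitivity halves when
        ``|log10(f / peak_sf)| = log_bandwidth / 2``.
    low_freq_truncation : float
        Fraction of ``peak_gain`` at which the low-frequency limb plateaus,
        in [0, 1]; 0 disables truncation.
    """

    peak_gain: float
    peak_sf: float
    log_bandwidth: float
    low_freq_truncation: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_gain <= 1:
            raise ValueError(f"peak_gain must be > 1, got {self.peak_gain}")
        if self.peak_sf <= 0:
            raise ValueError(f"peak_sf must be > 0, got {self.peak_sf}")
        if self.log_bandwidth <= 0:
            raise ValueError("log_bandwidth must be > 0")
        if not 0.0 <= self.low_freq_truncation <= 1.0:
            raise ValueError("low_freq_truncation must be in [0, 1]")

    def log_sensitivity(self, sf):
        """log10 sensitivity at spatial frequency ``sf`` (cpd, scalar or array)."""
        sf = np.asarray(sf, dtype=float)
        if np.any(sf <= 0):
            raise ValueError("spatial frequency must be positive")
        log_peak = math.log10(self.peak_gain)
        y = log_peak - _LOG_PARABOLA_K * (np.log10(sf / self.peak_sf) / self.log_bandwidth) ** 2
        if self.low_freq_truncation > 0:
            floor = math.log10(self.low_freq_truncation * self.peak_gain)
            y = np.where(sf < self.peak_sf, np.maximum(y, floor), y)
        return y if y.ndim else float(y)

    def sensitivity(self, sf):
        """Sensitivity (1 / contrast threshold) at ``sf`` cpd."""
        return 10.0 ** np.asarray(self.log_sensitivity(sf))

    def shifted(self, log10_attenuation: float) -> "TrueCSF":
        """Copy with peak gain attenuated by ``10**-log10_attenuation``."""
        return dataclasses.replace(
            self, peak_gain=self.peak_gain * 10.0 ** (-log10_attenuation)
        )


@dataclass(frozen=True)
class ObserverModel:
    """Generative truth for one eye: per-meridian CSF and sVEP parameters.

    The strong meridian is the higher-resolution one (vertical gratings in
    with-the-rule astigmatism); the weak meridian carries the configured
    meridional disparity. ``vep_threshold_*`` is the spatial frequency (cpd)
    at which the generative second-harmonic amplitude reaches zero.
    """

    csf_strong: TrueCSF
    csf_weak: TrueCSF
    psychometric_slope: float = 3.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.02
    vep_threshold_strong: float = 19.0
    vep_threshold_weak: float = 16.5
    vep_peak_amplitude: float = 4.0
    response_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be > 0")
        if self.guess_rate != 0.5:
            raise ValueError("guess_rate is fixed at 0.5 for 2IFC")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        for thr in (self.vep_threshold_strong, self.vep_threshold_weak):
            if thr <= 2.0:
                raise ValueError("vep thresholds must exceed 2 cpd")
        if self.vep_peak_amplitude < 0:
            raise ValueError("vep_peak_amplitude must be >= 0")

    def csf(self, meridian: Meridian) -> TrueCSF:
        if meridian == "strong":
            return self.csf_strong
        if meridian == "weak":
            return self.csf_weak
        raise ValueError(f"unknown meridian {meridian!r}")

    def vep_threshold(self, meridian: Meridian) -> float:
        if meridian == "strong":
            return self.vep_threshold_strong
        if meridian == "weak":
            return self.vep_threshold_weak
        raise ValueError(f"unknown meridian {meridian!r}")

    def contrast_threshold_at(self, p_target: float, sf: float,
                              meridian: Meridian) -> float:
        """Contrast at which P(correct) equals ``p_target`` (inverse psychometric)."""
        w = (p_target - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)
        if not 0.0 < w < 1.0:
            raise ValueError("p_target unreachable for this observer")
        tau = 1.0 / float(self.csf(meridian).sensitivity(sf))
        return tau * (-math.log1p(-w)) ** (1.0 / self.psychometric_slope)


def true_sensitivity(observer: ObserverModel, sf, meridian: Meridian):
    """Generative contrast sensitivity of ``observer`` at ``sf`` cpd."""
    return observer.csf(meridian).sensitivity(sf)


def p_correct(observer: ObserverModel, sf: float, contrast: float,
              meridian: Meridian) -> float:
    """Closed-form 2IFC probability of a correct response.

    P = guess + (1 - guess - lapse) * W(c), with Weibull
    W(c) = 1 - exp(-(c * S(sf))**slope) rising from 0 to 1.
    """
    if not 0.0 < contrast <= 1.0:
        raise ValueError(f"contrast must be in (0, 1], got {contrast}")
    s = float(observer.csf(meridian).sensitivity(sf))
    w = 1.0 - math.exp(-((contrast * s) ** observer.psychometric_slope))
    return observer.guess_rate + (1.0 - observer.guess_rate - observer.lapse_rate) * w


def simulate_2ifc_trial(observer: ObserverModel, sf: float, contrast: float,
                        meridian: Meridian, rng: np.random.Generator) -> bool:
    """Draw one Bernoulli 2IFC outcome at the given contrast."""
    return bool(rng.random() < p_correct(observer, sf, contrast, meridian))


# ---------------------------------------------------------------------------
# sweep-VEP stimulus and EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepStimulus:
    """Spatial-frequency sweep stimulus: an 80%-contrast 6 Hz phase-reversing
    grating swept from 2 to 16 cpd in 10 linear steps over a 10 s trial,
    repeated 10 times."""

    contrast: float = 0.80
    temporal_freq: float = 6.0
    sweep_start: float = 2.0
    sweep_end: float = 16.0
    n_steps: int = 10
    duration: float = 10.0
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.sweep_end <= self.sweep_start:
            raise ValueError("sweep_end must exceed sweep_start")
        if self.duration <= 0 or self.n_repeats < 1:
            raise ValueError("invalid duration or n_repeats")

    @property
    def step_frequencies(self) -> np.ndarray:
        """The swept spatial frequencies, strictly increasing, endpoints included."""
        return np.linspace(self.sweep_start, self.sweep_end, self.n_steps)

    @property
    def epoch_duration(self) -> float:
        return self.duration / self.n_steps

    @property
    def second_harmonic(self) -> float:
        """Analysis frequency: twice the phase-reversal (temporal) frequency."""
        return 2.0 * self.temporal_freq


@dataclass(frozen=True)
class NoiseConfig:
    """Background-EEG noise model: 1/f^alpha Gaussian plus white noise.

    ``pink_rms``/``white_rms`` are per-channel RMS amplitudes in microvolts;
    ``phase_jitter_sd`` (radians) jitters the response phase once per trial.
    """

    one_over_f_exponent: float = 1.0
    pink_rms: float = 10.0
    white_rms: float = 5.0
    phase_jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.pink_rms < 0 or self.white_rms < 0 or self.phase_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class EEGTrial:
    """One sweep trial of multichannel EEG (channels x samples, microvolts)."""

    samples: np.ndarray
    channel_names: tuple
    sampling_rate: float
    stimulus: SweepStimulus
    meridian: Meridian
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError("samples must be channels x time")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        n_expected = int(round(self.sampling_rate * self.stimulus.duration))
        if self.samples.shape[1] != n_expected:
            raise ValueError(
                f"expected {n_expected} samples, got {self.samples.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in trial") from None

    # -- text serialization: matrix file + JSON sidecar ---------------------
    def save(self, path_prefix) -> tuple:
        """Write ``<prefix>.dat`` (whitespace matrix, channels x samples) and
        ``<prefix>.json`` (sidecar with channels, rate, sweep, meridian, seed)."""
        prefix = Path(path_prefix)
        dat, sidecar = prefix.with_suffix(".dat"), prefix.with_suffix(".json")
        np.savetxt(dat, self.samples, fmt="%.10e")
        meta = {
            "channel_names": list(self.channel_names),
            "sampling_rate": self.sampling_rate,
            "stimulus": dataclasses.asdict(self.stimulus),
            "meridian": self.meridian,
            "seed": self.seed,
        }
        sidecar.write_text(json.dumps(meta, indent=1))
        return dat, sidecar

    @classmethod
    def load(cls, path_prefix) -> "EEGTrial":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        samples = np.loadtxt(prefix.with_suffix(".dat"), ndmin=2)
        return cls(
            samples=samples,
            channel_names=tuple(meta["channel_names"]),
            sampling_rate=meta["sampling_rate"],
            stimulus=SweepStimulus(**meta["stimulus"]),
            meridian=meta["meridian"],
            seed=meta["seed"],
        )


def second_harmonic_amplitude(observer: ObserverModel, sf: float,
                              stimulus: SweepStimulus,
                              meridian: Meridian) -> float:
    """Generative 12 Hz amplitude at swept frequency ``sf``: linear descent
    from ``vep_peak_amplitude`` at the first swept value to zero at the
    observer's generative threshold."""
    f_thr = observer.vep_threshold(meridian)
    f_ref = stimulus.sweep_start
    return observer.vep_peak_amplitude * max(0.0, (f_thr - sf) / (f_thr - f_ref))


def _one_over_f_noise(n: int, exponent: float, rms: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with 1/f^exponent power spectrum, scaled to target RMS."""
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def generate_sweep_trial(observer: ObserverModel, stimulus: SweepStimulus,
                         meridian: Meridian, noise_cfg: NoiseConfig,
                         rng, sampling_rate: float = 2048.0,
                         channels: Sequence[str] = OCCIPITAL_CHANNELS) -> EEGTrial:
    """Generate one sweep trial of EEG.

    Each of the ``n_steps`` epochs carries a second-harmonic sinusoid whose
    amplitude follows the observer's linear amplitude-vs-frequency law, with
    the observer's response phase plus one per-trial jitter draw; the response
    is present only on the occipital channels (Oz, O1, O2). All channels get
    independent 1/f-shaped plus white Gaussian noise.
    """
    channels = tuple(channels)
    missing = [c for c in OCCIPITAL_CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"channel config must include {missing}")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    n = int(round(sampling_rate * stimulus.duration))
    n_epoch = n // stimulus.n_steps
    if n_epoch * stimulus.n_steps != n:
        raise ValueError("trial length not divisible into equal epochs")
    t = np.arange(n) / sampling_rate

    phase = observer.response_phase
    if noise_cfg.phase_jitter_sd > 0:
        phase = phase + rng.normal(0.0, noise_cfg.phase_jitter_sd)

    amplitude = np.repeat(
        [second_harmonic_amplitude(observer, f, stimulus, meridian)
         for f in stimulus.step_frequencies],
        n_epoch,
    )
    response = amplitude * np.cos(2.0 * np.pi * stimulus.second_harmonic * t + phase)

    samples = np.empty((len(channels), n))
    for i, name in enumerate(channels):
        noise = _one_over_f_noise(n, noise_cfg.one_over_f_exponent,
                                  noise_cfg.pink_rms, sampling_rate, rng)
        if noise_cfg.white_rms > 0:
            noise = noise + rng.normal(0.0, noise_cfg.white_rms, n)
        samples[i] = noise
        if name in OCCIPITAL_CHANNELS:
            samples[i] += response

    return EEGTrial(samples=samples, channel_names=channels,
                    sampling_rate=sampling_rate, stimulus=stimulus,
                    meridian=meridian, seed=seed)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one group of eyes.

    CSF disparity is a vertical log10-sensitivity shift applied to the weak
    meridian (clipped at 0 so weak <= strong holds eye by eye); sVEP disparity
    is subtracted from the strong-meridian generative threshold.
    """

    name: str
    n_eyes: int
    peak_gain_log10_mean: float = math.log10(45.0)
    peak_gain_log10_sd: float = 0.08
    peak_sf: float = 3.0
    log_bandwidth: float = 1.0
    low_freq_truncation: float = 0.3
    csf_disparity_mean: float = 0.15
    csf_disparity_sd: float = 0.05
    vep_threshold_mean: float = 19.2
    vep_threshold_sd: float = 1.5
    vep_disparity_mean: float = 2.6
    vep_disparity_sd: float = 0.8
    vep_peak_amplitude_mean: float = 4.0
    vep_peak_amplitude_sd: float = 0.5
    psychometric_slope: float = 3.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_eyes <= 0:
            raise ValueError("group size must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort; defaults mirror the study layout: an astigmatism
    (AST) group of 20 eyes with moderate meridional disparity and a meridional
    amblyopia (MA) group of 19 eyes with larger disparity."""

    groups: tuple = (
        GroupSpec(name="AST", n_eyes=20,
                  csf_disparity_mean=0.15, vep_threshold_mean=19.2,
                  vep_disparity_mean=2.6),
        GroupSpec(name="MA", n_eyes=19,
                  peak_gain_log10_mean=math.log10(32.0),
                  csf_disparity_mean=0.26, vep_threshold_mean=17.1,
                  vep_disparity_mean=2.3),
    )


@dataclass(frozen=True)
class EyeRecord:
    eye_id: str
    group: str
    observer: ObserverModel


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> list:
    """Draw a reproducible cohort of per-eye observers with group labels."""
    eyes: list[EyeRecord] = []
    for g in spec.groups:
        for i in range(g.n_eyes):
            log_gain = rng.normal(g.peak_gain_log10_mean, g.peak_gain_log10_sd)
            strong = TrueCSF(peak_gain=10.0 ** log_gain, peak_sf=g.peak_sf,
                             log_bandwidth=g.log_bandwidth,
                             low_freq_truncation=g.low_freq_truncation)
            d_csf = max(0.0, rng.normal(g.csf_disparity_mean, g.csf_disparity_sd))
            weak = strong.shifted(d_csf)
            thr_strong = max(4.0, rng.normal(g.vep_threshold_mean, g.vep_threshold_sd))
            d_vep = max(0.0, rng.normal(g.vep_disparity_mean, g.vep_disparity_sd))
            thr_weak = max(2.5, thr_strong - d_vep)
            obs = ObserverModel(
                csf_strong=strong, csf_weak=weak,
                psychometric_slope=g.psychometric_slope, lapse_rate=g.lapse_rate,
                vep_threshold_strong=thr_strong, vep_threshold_weak=thr_weak,
                vep_peak_amplitude=max(1.0, rng.normal(g.vep_peak_amplitude_mean,
                                                       g.vep_peak_amplitude_sd)),
                response_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
            )
            eyes.append(EyeRecord(eye_id=f"{g.name}-{i + 1:02d}", group=g.name,
                                  observer=obs))
    return eyes


def default_observer() -> ObserverModel:
    """A canonical mid-range observer used by examples and simulations."""
    strong = TrueCSF(peak_gain=45.0, peak_sf=3.0, log_bandwidth=1.0,
                     low_freq_truncation=0.3)
    return ObserverModel(csf_strong=strong, csf_weak=strong.shifted(0.15),
                         vep_threshold_strong=19.2, vep_threshold_weak=16.6)
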