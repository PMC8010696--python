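"""Sweep-VEP analysis: filtering, epoching, recursive-least-squares harmonic
coefficients, coherent averaging, SNR gating, and regression-to-zero
threshold estimation.

The analysis chain mirrors standard steady-state VEP practice: each 10 s
sweep trial is band-pass filtered (1-30 Hz, zero phase), cut into one
epoch per swept spatial frequency, and each epoch's complex second-harmonic
coefficient (12 Hz for a 6 Hz phase-reversing stimulus) is extracted by a
recursive least squares (RLS) fit of sine/cosine regressors. Coefficients
are averaged across the occipital electrodes (Oz, O1, O2), coherently
(vector) averaged across trial repeats, gated by a 3:1 signal-to-noise
criterion against the adjacent 11 and 13 Hz bins, and the spatial-frequency
threshold is the zero-amplitude intercept of a straight-line fit to the
amplitude-vs-frequency sweep function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .synthetic_data import EEGTrial, OCCIPITAL_CHANNELS


def sweep_frequencies(start: float = 2.0, end: float = 16.0,
                      n: int = 10) -> np.ndarray:
    """The swept spatial frequencies: ``n`` equally spaced values from
    ``start`` to ``end`` inclusive (step (end-start)/(n-1))."""
    if n < 2:
        raise ValueError("need at least 2 sweep steps")
    if end <= start:
        raise ValueError("sweep end must exceed start")
    return np.linspace(start, end, n)


def analysis_bandpass(trial: EEGTrial, low: float = 1.0, high: float = 30.0,
                      order: int = 4) -> EEGTrial:
    """Zero-phase Butterworth band-pass of a whole trial (all channels)."""
    nyq = trial.sampling_rate / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for fs={trial.sampling_rate}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trial.sampling_rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, trial.samples, axis=1)
    return EEGTrial(samples=filtered, channel_names=trial.channel_names,
                    sampling_rate=trial.sampling_rate, stimulus=trial.stimulus,
                    meridian=trial.meridian, seed=trial.seed)


def epoch_trial(trial: EEGTrial) -> tuple:
    """Split a trial into its ``n_steps`` contiguous epochs.

    Returns ``(swept_sfs, epochs)`` with ``epochs`` shaped
    (n_steps, n_channels, samples_per_epoch); epoch k corresponds to swept
    frequency k.
    """
    n_steps = trial.stimulus.n_steps
    n = trial.n_samples
    if n % n_steps != 0:
        raise ValueError(f"{n} samples not divisible into {n_steps} epochs")
    epochs = trial.samples.reshape(len(trial.channel_names), n_steps, -1)
    return trial.stimulus.step_frequencies, np.swapaxes(epochs, 0, 1)


@njit(cache=True)
def _rls_recursion(X, y, lam, delta):  # pragma: no cover - compiled
    n, p = X.shape
    P = np.eye(p) * delta
    theta = np.zeros(p)
    for t in range(n):
        x = X[t]
        Px = P @ x
        denom = lam + x @ Px
        g = Px / denom
        err = y[t] - x @ theta
        theta = theta + g * err
        P = (P - np.outer(g, Px)) / lam
    return theta


def rls_coefficients(samples: np.ndarray, f_targets: Sequence[float],
                     sampling_rate: float, forgetting_factor: float = 1.0,
                     _init_gain: float = 1e8) -> dict:
    """Complex spectral coefficients of one epoch by recursive least squares.

    Fits y(t) ~= sum_j a_j cos(2 pi f_j t) + b_j sin(2 pi f_j t) sample by
    sample with exponential forgetting and returns ``{f_j: a_j - i b_j}``
    read out at the epoch end, so the modulus is the component's amplitude
    and the argument its phase. With ``forgetting_factor=1`` the recursion
    converges to the ordinary least-squares projection on the epoch.
    """
    y = np.asarray(samples, float)
    if y.ndim != 1:
        raise ValueError("samples must be a single-channel 1-D epoch")
    freqs = [float(f) for f in f_targets]
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate target frequencies make the design singular")
    if any(f >= sampling_rate / 2.0 for f in freqs):
        raise ValueError("target frequency at or above Nyquist")
    if not 0.9 < forgetting_factor <= 1.0:
        raise ValueError("forgetting_factor must be in (0.9, 1]")

    t = np.arange(y.size) / sampling_rate
    X = np.empty((y.size, 2 * len(freqs)))
    for j, f in enumerate(freqs):
        X[:, 2 * j] = np.cos(2.0 * np.pi * f * t)
        X[:, 2 * j + 1] = np.sin(2.0 * np.pi * f * t)
    theta = _rls_recursion(X, y, forgetting_factor, _init_gain)
    return {f: complex(theta[2 * j], -theta[2 * j + 1])
            for j, f in enumerate(freqs)}


@dataclass(frozen=True)
class EpochSpectrum:
    """Complex harmonic coefficients of one epoch on one channel (or the
    occipital mean)."""

    epoch_index: int
    swept_sf: float
    coefficients: dict
    channel: str = "occipital-mean"


def occipital_average(per_channel: Mapping[str, Mapping[float, complex]],
                      channels: Sequence[str] = OCCIPITAL_CHANNELS) -> dict:
    """Complex mean of the three occipital channels' coefficients."""
    missing = [c for c in channels if c not in per_channel]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    freqs = list(per_channel[channels[0]].keys())
    return {f: sum(per_channel[c][f] for c in channels) / len(channels)
            for f in freqs}


def coherent_average(per_trial: np.ndarray) -> tuple:
    """Vector mean and vector standard error across trials.

    ``per_trial`` is complex, shaped (n_trials, n_epochs). The vector SE of
    the mean pools the sample variances of the real and imaginary parts:
    SE = sqrt((var(Re) + var(Im)) / n).
    """
    z = np.asarray(per_trial)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a (n_trials >= 2, n_epochs) coefficient array")
    mean = z.mean(axis=0)
    n = z.shape[0]
    var = z.real.var(axis=0, ddof=1) + z.imag.var(axis=0, ddof=1)
    se = np.sqrt(var / n)
    return mean, se


def noise_and_snr(signal_amplitude: np.ndarray,
                  noise_coefficients: Mapping[float, np.ndarray]) -> tuple:
    """Per-epoch noise amplitude and SNR.

    Noise amplitude is the mean modulus of the vector-averaged coefficients
    at the adjacent frequencies; SNR is signal/noise with +inf where the
    noise amplitude is exactly zero.
    """
    amps = [np.abs(np.asarray(v)) for v in noise_coefficients.values()]
    noise = np.mean(amps, axis=0)
    sig = np.asarray(signal_amplitude, float)
    with np.errstate(divide="ignore"):
        snr = np.where(noise > 0, sig / np.where(noise > 0, noise, 1.0), np.inf)
    return noise, snr


@dataclass(frozen=True)
class SweepResponse:
    """Trial-averaged sweep response function at the second harmonic."""

    sfs: np.ndarray               # swept spatial frequencies, cpd
    vector_mean: np.ndarray       # complex, per epoch
    vector_se: np.ndarray         # microvolts
    noise_amplitude: np.ndarray   # microvolts
    snr: np.ndarray
    n_trials: int

    @property
    def amplitude(self) -> np.ndarray:
        """Modulus of the coherent (vector) mean, microvolts."""
        return np.abs(self.vector_mean)


@dataclass(frozen=True)
class VEPThresholdFit:
    """Regression-to-zero threshold fit over the SNR-gated scoring window."""

    included_epochs: tuple
    slope: float                  # microvolts per cpd, < 0 when valid
    intercept_sf: float           # cpd; nan when invalid
    valid: bool
    reason: str = ""


def estimate_svep_threshold(response: SweepResponse,
                            criterion_snr: float = 3.0) -> VEPThresholdFit:
    """Spatial-frequency threshold by linear regression of amplitude on sf.

    The scoring window runs from the highest-amplitude epoch whose SNR
    exceeds the criterion through the last subsequent epoch exceeding it;
    an ordinary least-squares line over the window is extrapolated to zero
    amplitude (beyond the sweep end when needed). Fits with fewer than three
    window epochs or a non-negative slope are flagged invalid.
    """
    amp = response.amplitude
    ok = response.snr > criterion_snr
    if not ok.any():
        return VEPThresholdFit((), math.nan, math.nan, False, "no-signal-window")
    candidates = np.flatnonzero(ok)
    start = candidates[np.argmax(amp[candidates])]
    end = candidates[-1]
    window = tuple(range(start, end + 1))
    if len(window) < 3:
        return VEPThresholdFit(window, math.nan, math.nan, False,
                               "window-too-short")
    idx = list(window)
    slope, intercept = np.polyfit(response.sfs[idx], amp[idx], 1)
    if slope >= 0:
        return VEPThresholdFit(window, float(slope), math.nan, False,
                               "non-negative-slope")
    return VEPThresholdFit(window, float(slope), float(-intercept / slope), True)


class SweepVEPAnalyzer(BaseEstimator):
    """End-to-end sweep-VEP analysis of repeated EEG trials.

    Parameters
    ----------
    temporal_freq : float
        Stimulus phase-reversal frequency, Hz; the analysis frequency is its
        second harmonic (``harmonic * temporal_freq``).
    harmonic : int
        Harmonic analyzed (2 -> 12 Hz for a 6 Hz stimulus).
    noise_freqs : tuple of float or None
        Adjacent noise bins; None means signal frequency +- 1 Hz.
    criterion_snr : float
        SNR validity gate (signal amplitude over adjacent-bin noise).
    forgetting_factor : float
        RLS exponential-forgetting constant, in (0.9, 1]; 1 reproduces the
        per-epoch least-squares projection.
    band : tuple or None
        Analysis band-pass in Hz (None disables filtering).
    channels : tuple of str
        Electrodes averaged before trial averaging.

    Attributes (after :meth:`fit`)
    ------------------------------
    signal_freq_ : float — analysis frequency in Hz
    sweep_sfs_ : ndarray — swept spatial frequencies, cpd
    amplitudes_ : ndarray — vector-mean amplitude per epoch, microvolts
    vector_se_, noise_amplitudes_, snr_ : ndarray per epoch
    response_ : SweepResponse
    fit_ : VEPThresholdFit
    threshold_ : float — cpd (nan when invalid)
    valid_ : bool
    """

    def __init__(self, temporal_freq: float = 6.0, harmonic: int = 2,
                 noise_freqs: tuple | None = None, criterion_snr: float = 3.0,
                 forgetting_factor: float = 1.0, band: tuple | None = (1.0, 30.0),
                 filter_order: int = 4,
                 channels: tuple = OCCIPITAL_CHANNELS):
        self.temporal_freq = temporal_freq
        self.harmonic = harmonic
        self.noise_freqs = noise_freqs
        self.criterion_snr = criterion_snr
        self.forgetting_factor = forgetting_factor
        self.band = band
        self.filter_order = filter_order
        self.channels = channels

    @property
    def signal_freq(self) -> float:
        """Analysis frequency in Hz: the chosen harmonic of the stimulus
        phase-reversal rate (12 Hz for the default 6 Hz second harmonic)."""
        return float(self.harmonic * self.temporal_freq)

    def _target_freqs(self) -> tuple:
        f_sig = self.signal_freq
        noise = self.noise_freqs
        if noise is None:
            noise = (f_sig - 1.0, f_sig + 1.0)
        return f_sig, tuple(noise)

    def fit(self, X, y=None) -> "SweepVEPAnalyzer":
        """Analyze a sequence of repeated :class:`EEGTrial` sweeps."""
        trials = list(X)
        if len(trials) < 2:
            raise ValueError("need at least 2 trial repeats for vector averaging")
        ref = trials[0]
        for tr in trials[1:]:
            if (tr.n_samples != ref.n_samples
                    or tr.sampling_rate != ref.sampling_rate
                    or tr.stimulus != ref.stimulus):
                raise ValueError("trials have mismatched structure")

        f_sig, f_noise = self._target_freqs()
        targets = (f_sig,) + f_noise
        coeffs = {f: np.empty((len(trials), ref.stimulus.n_steps), complex)
                  for f in targets}
        for i, tr in enumerate(trials):
            if self.band is not None:
                tr = analysis_bandpass(tr, *self.band, order=self.filter_order)
            sfs, epochs = epoch_trial(tr)
            for k in range(epochs.shape[0]):
                per_channel = {
                    name: rls_coefficients(epochs[k, j], targets,
                                           tr.sampling_rate,
                                           self.forgetting_factor)
                    for j, name in enumerate(tr.channel_names)
                }
                pooled = occipital_average(per_channel, self.channels)
                for f in targets:
                    coeffs[f][i, k] = pooled[f]

        mean_sig, se = coherent_average(coeffs[f_sig])
        noise_means = {f: coherent_average(coeffs[f])[0] for f in f_noise}
        noise, snr = noise_and_snr(np.abs(mean_sig), noise_means)

        self.signal_freq_ = f_sig
        self.sweep_sfs_ = sfs
        self.response_ = SweepResponse(sfs=sfs, vector_mean=mean_sig,
                                       vector_se=se, noise_amplitude=noise,
                                       snr=snr, n_trials=len(trials))
        self.amplitudes_ = self.response_.amplitude
        self.vector_se_ = se
        self.noise_amplitudes_ = noise
        self.snr_ = snr
        self.fit_ = estimate_svep_threshold(self.response_, self.criterion_snr)
        self.threshold_ = self.fit_.intercept_sf
        self.valid_ = self.fit_.valid
        return self
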