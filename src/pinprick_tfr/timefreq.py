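"""Morlet-wavelet time-frequency decomposition and dB normalization.

Power is extracted by convolving each epoch with complex Morlet wavelets

    w(t) = exp(i 2 pi f t) * exp(-t^2 / (2 * (10 / (2 pi f))^2))

at 30 logarithmically spaced frequencies from 1 to 35 Hz, i.e. a
Gaussian-windowed complex sine whose temporal SD is sigma_t(f) = 10/(2 pi f)
seconds (a fixed 10-cycle width). Trial-averaged power is normalized to
decibels against the frequency-specific mean power in the -0.4 to -0.1 s
pre-stimulus baseline:

    dB(f, t) = 10 * log10( P(f, t) / mean_{t in baseline} P(f, t) ).

The dB map is invariant to any rescaling of the input signal and to the
wavelet amplitude normalization (unit energy here), since per-frequency
scale factors cancel in the baseline ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ParameterError, PipelineError, SAMPLING_RATE

N_FREQS = 30
F_MIN, F_MAX = 1.0, 35.0


def morlet_frequencies(n: int = N_FREQS, f_min: float = F_MIN, f_max: float = F_MAX) -> np.ndarray:
    """The analysis grid: f_k = f_min * (f_max/f_min)^(k/(n-1)), k = 0..n-1."""
    return f_min * (f_max / f_min) ** (np.arange(n) / (n - 1))


def sigma_t(freqs: np.ndarray) -> np.ndarray:
    """Temporal SD of the Gaussian envelope at each frequency (s)."""
    return 10.0 / (2.0 * np.pi * np.asarray(freqs))


@dataclass
class WaveletFamily:
    frequencies: np.ndarray = field(default_factory=morlet_frequencies)
    cycles_constant: float = 10.0
    support_sigmas: float = 5.0  # kernel truncated at +- this many sigma_t
    sampling_rate: float = SAMPLING_RATE

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if not np.all(np.diff(f) > 0):
            raise ParameterError("frequencies must be strictly increasing")
        if np.any(sigma_t(f) * self.sampling_rate < 2):
            raise ParameterError("sigma_t must exceed 2 sample periods at every frequency")
        if self.support_sigmas < 3:
            raise ParameterError("wavelet support must cover at least +-3 sigma_t")
        self.frequencies = f


@dataclass
class EpochWindowTF:
    start: float = -1.5
    end: float = 2.2
    db_baseline: tuple[float, float] = (-0.4, -0.1)
    analysis: tuple[float, float] = (0.0, 1.6)

    def __post_init__(self) -> None:
        b0, b1 = self.db_baseline
        if not (self.start <= b0 < b1 <= 0):
            raise ParameterError("dB baseline must lie within [start, 0]")
        a0, a1 = self.analysis
        if not (0 <= a0 < a1 <= self.end):
            raise ParameterError("analysis window must lie within [0, end]")


@dataclass
class TFRMatrix:
    """Frequency x time power map for one participant/channel/condition."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s relative to stimulus
    units: str  # "uV^2" or "dB"
    labels: dict = field(default_factory=dict)
    edge_samples: np.ndarray | None = None  # per-frequency count of edge-contaminated bins

    def edge_mask(self) -> np.ndarray:
        """Boolean (n_freqs, n_times): True where convolution edges reach.

        At the lowest frequencies the kernel is longer than the pre-stimulus
        padding, so the earliest and latest bins are flagged (not trimmed)."""
        mask = np.zeros_like(self.values, dtype=bool)
        if self.edge_samples is not None:
            for i, k in enumerate(self.edge_samples):
                if k > 0:
                    mask[i, :k] = True
                    mask[i, -k:] = True
        return mask


def build_wavelets(family: WaveletFamily) -> list[np.ndarray]:
    """One complex, unit-energy Morlet kernel per frequency.

    Each kernel is exp(i 2 pi f t) times a Gaussian of SD 10/(2 pi f),
    sampled at the family's rate over +- support_sigmas * sigma_t of its own
    frequency and scaled to unit energy (sum |w|^2 = 1).
    """
    kernels = []
    for f in family.frequencies:
        st = 10.0 / (2.0 * np.pi * f)
        half = int(np.ceil(family.support_sigmas * st * family.sampling_rate))
        t = np.arange(-half, half + 1) / family.sampling_rate
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * st**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        kernels.append(w)
    return kernels


def tfr_power(epochs: np.ndarray, times: np.ndarray,
              family: WaveletFamily | None = None, labels: dict | None = None) -> TFRMatrix:
    """Raw trial-averaged wavelet power of single-channel epochs.

    ``epochs`` is (n_trials, n_samples). Per trial and frequency, the signal
    is convolved ('same' length, FFT-based) with the complex kernel and the
    squared magnitude taken; trials are then averaged. Bins within
    3 sigma_t(f) of either epoch edge are recorded in ``edge_samples``.
    """
    family = family or WaveletFamily()
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    kernels = build_wavelets(family)
    n_samp = epochs.shape[1]
    min_len = int(np.ceil(2 * sigma_t(family.frequencies[0]) * family.sampling_rate))
    if n_samp < min_len:
        raise PipelineError(
            f"epochs of {n_samp} samples cannot support the lowest-frequency "
            f"wavelet (needs >= {min_len})")
    power = np.empty((len(kernels), n_samp))
    for i, k in enumerate(kernels):
        if len(k) > n_samp:  # keep the kernel no longer than the epoch
            trim = (len(k) - n_samp + 1) // 2
            k = k[trim:len(k) - trim]
        conv = signal.fftconvolve(epochs, k[None, :], mode="same", axes=1)
        power[i] = np.mean(np.abs(conv) ** 2, axis=0)
    edge = np.minimum(
        np.ceil(3 * sigma_t(family.frequencies) * family.sampling_rate).astype(int),
        n_samp // 2)
    return TFRMatrix(power, family.frequencies.copy(), np.asarray(times, dtype=float),
                     units="uV^2", labels=dict(labels or {}), edge_samples=edge)


def tfr_power_continuous(x: np.ndarray, sfreq: float, onsets: np.ndarray,
                         window: EpochWindowTF | None = None,
                         family: WaveletFamily | None = None,
                         labels: dict | None = None) -> TFRMatrix:
    """Raw trial-averaged power via convolution of the continuous channel.

    Convolving the whole cleaned channel once per frequency and epoching the
    power afterwards is the same computation as epoch-wise convolution with
    the epoch padded by the true neighboring data, and therefore has no
    artificial edge effects inside the epoch (only events closer than the
    kernel half-width to a recording boundary are skipped).
    """
    window = window or EpochWindowTF()
    family = family or WaveletFamily()
    x = np.asarray(x, dtype=float)
    kernels = build_wavelets(family)
    i0 = int(round(window.start * sfreq))
    i1 = int(round(window.end * sfreq))
    times = (np.arange(i1 - i0) + i0) / sfreq
    half = max(len(k) for k in kernels) // 2
    onsets = np.asarray(onsets, dtype=int)
    ok = (onsets + i0 - half >= 0) & (onsets + i1 + half <= len(x))
    use = onsets[ok]
    if use.size == 0:
        raise PipelineError("no events far enough from the recording edges")
    idx = use[:, None] + np.arange(i0, i1)[None, :]
    power = np.empty((len(kernels), i1 - i0))
    for i, k in enumerate(kernels):
        p = np.abs(signal.fftconvolve(x, k, mode="same")) ** 2
        power[i] = p[idx].mean(axis=0)
    lab = {"n_trials": int(use.size), **(labels or {})}
    return TFRMatrix(power, family.frequencies.copy(), times, units="uV^2",
                     labels=lab, edge_samples=None)


def db_normalize(tfr: TFRMatrix, window: EpochWindowTF | None = None) -> TFRMatrix:
    """Decibel normalization against the pre-stimulus baseline.

    dB(f,t) = 10*log10(P(f,t) / mean of P(f, baseline)); exact contract:
    the baseline mean of the power ratio is 1 at every frequency.
    """
    window = window or EpochWindowTF()
    if tfr.units == "dB":
        raise ParameterError("TFR is already dB-normalized")
    b0, b1 = window.db_baseline
    bmask = (tfr.times >= b0) & (tfr.times < b1)
    if not bmask.any():
        raise ParameterError("baseline interval outside epoch")
    base = tfr.values[:, bmask].mean(axis=1, keepdims=True)
    if np.any(base <= 0):
        raise PipelineError("zero baseline power at some frequency")
    vals = 10.0 * np.log10(tfr.values / base)
    return TFRMatrix(vals, tfr.freqs.copy(), tfr.times.copy(), units="dB",
                     labels=dict(tfr.labels), edge_samples=tfr.edge_samples)


def epoch_tfr(recording, events, hand: str, channel: str,
              window: EpochWindowTF | None = None,
              family: WaveletFamily | None = None,
              per_trial_normalize: bool = False, labels: dict | None = None) -> TFRMatrix:
    """Convenience: dB time-frequency map for one hand/channel condition.

    Power comes from continuous-channel convolution (no epoch-edge
    artifacts); normalization is trial-average-then-dB by default (the
    per-trial option dB-normalizes each trial's power before averaging,
    which requires epoch-wise convolution).
    """
    from .timedomain import EpochWindowTD, extract_epochs

    window = window or EpochWindowTF()
    family = family or WaveletFamily()
    onsets = events.loc[events["hand"] == hand, "onset_sample"].to_numpy()
    if onsets.size == 0:
        raise PipelineError(f"no epochs for hand {hand!r}")
    lab = {"hand": hand, "channel": channel, **(labels or {})}
    if per_trial_normalize:
        td = EpochWindowTD(window.start, window.end, baseline=(window.start, 0.0))
        eps = extract_epochs(recording, events, td, baseline_correct=False)
        sel = eps.hands == hand
        x = eps.data[sel, eps.ch_names.index(channel), :]
        mats = [db_normalize(tfr_power(x[i:i + 1], eps.times, family, lab), window).values
                for i in range(x.shape[0])]
        raw = tfr_power(x, eps.times, family, lab)
        return TFRMatrix(np.mean(mats, axis=0), raw.freqs, raw.times, "dB", lab,
                         raw.edge_samples)
    raw = tfr_power_continuous(recording.pick(channel), recording.sfreq,
                               onsets, window, family, lab)
    return db_normalize(raw, window)
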