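"""Continuous-EEG cleaning: band-pass FIR, bad channels, CAR, bad segments.

The chain is: zero-phase 1-35 Hz FIR band-pass, removal of noisy channels
(robust-variance / neighbor-correlation criteria), common-average
re-reference over the retained channels, and excision of high-amplitude data
spans with re-indexing of the stimulus events. The channel and segment
criteria are deterministic, documented stand-ins for the proprietary
cleaning tools used in clinical practice; an explicit no-op hook marks where
an ICA stage could be inserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import CENTRAL_CHANNELS, ParameterError, PipelineError, Recording

#: Full time-frequency epoch window; events whose epoch touches an excised
#: span are dropped during segment rejection.
TF_EPOCH = (-1.5, 2.2)


@dataclass
class PreprocConfig:
    band: tuple[float, float] = (1.0, 35.0)
    transition: float = 1.0  # Hz, at the low edge; sets the FIR order
    bad_channel_zscore: float = 3.5
    neighbor_corr_min: float = 0.4
    segment_ptp_max: float = 200.0  # µV peak-to-peak
    segment_window: float = 1.0  # s
    segment_step: float = 0.25  # s

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ParameterError("band must satisfy 0 < low < high")


def _fir_taps(config: PreprocConfig, sfreq: float) -> np.ndarray:
    lo, hi = config.band
    if hi >= sfreq / 2:
        raise ParameterError("band must lie below the Nyquist frequency")
    # Hamming windowed-sinc; ~3.3/N normalized transition width.
    numtaps = int(np.ceil(3.3 * sfreq / config.transition))
    numtaps += 1 - numtaps % 2  # odd -> exactly linear phase, integer delay
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=sfreq)


def bandpass_filter(recording: Recording, config: PreprocConfig | None = None) -> Recording:
    """Zero-phase (forward-backward) FIR band-pass, applied per channel.

    Forward-backward filtering with a linear-phase FIR equals a single
    zero-phase convolution with the filter's autocorrelation, which is how it
    is computed here (FFT overlap-add); stop-band attenuation is doubled
    relative to the one-pass design.
    """
    config = config or PreprocConfig()
    h = _fir_taps(config, recording.sfreq)
    h2 = np.convolve(h, h[::-1])  # symmetric, zero-phase when applied 'same'
    out = recording.copy()
    out.data = signal.oaconvolve(out.data, h2[None, :], mode="same", axes=1)
    out.meta.setdefault("log", []).append(
        {"stage": "bandpass", "band": list(config.band), "numtaps": len(h)})
    return out


def detect_bad_channels(recording: Recording, config: PreprocConfig | None = None) -> set[str]:
    """Channels with outlying robust log-variance or no correlated neighbor.

    A channel is flagged when the robust z-score (median/MAD) of its
    log-variance exceeds ``bad_channel_zscore``, or when its best absolute
    Pearson correlation with any other channel falls below
    ``neighbor_corr_min``. Flagging C3 or C4 raises a warning because the
    downstream analysis needs them.
    """
    config = config or PreprocConfig()
    if recording.n_channels < 4:
        raise ParameterError("bad-channel detection needs >= 4 channels")
    logvar = np.log(np.var(recording.data, axis=1))
    med = np.median(logvar)
    # MAD floored at 0.1 log-units so near-identical clean channels are not
    # flagged on minuscule fluctuations
    mad = max(np.median(np.abs(logvar - med)) * 1.4826, 0.1)
    z = (logvar - med) / mad
    corr = np.corrcoef(recording.data)
    np.fill_diagonal(corr, 0.0)
    best = np.max(np.abs(corr), axis=1)
    bad = {name for name, zi, bi in zip(recording.ch_names, z, best)
           if abs(zi) > config.bad_channel_zscore or bi < config.neighbor_corr_min}
    if bad >= set(recording.ch_names):
        raise PipelineError("all channels flagged as bad")
    for ch in bad & set(CENTRAL_CHANNELS):
        warnings.warn(f"central channel {ch} flagged bad; downstream analysis requires it",
                      stacklevel=2)
    return bad


def rereference_car(recording: Recording, excluded: set[str] | None = None) -> Recording:
    """Common-average re-reference over retained channels.

    Excluded (bad) channels are dropped; every retained channel has the
    instantaneous mean across retained channels subtracted, so the channel
    mean is zero at every sample.
    """
    excluded = excluded or set()
    keep = [i for i, name in enumerate(recording.ch_names) if name not in excluded]
    if len(keep) < 2:
        raise PipelineError("common-average reference needs >= 2 retained channels")
    data = recording.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    out = Recording(data, recording.sfreq,
                    [recording.ch_names[i] for i in keep], dict(recording.meta))
    out.meta.setdefault("log", []).append(
        {"stage": "car", "excluded": sorted(excluded)})
    return out


def ica_hook(recording: Recording) -> Recording:
    """No-op placeholder where an ICA artifact-removal stage could be inserted."""
    return recording


def _bad_spans(data: np.ndarray, sfreq: float, config: PreprocConfig) -> list[tuple[int, int]]:
    win = int(round(config.segment_window * sfreq))
    step = int(round(config.segment_step * sfreq))
    n = data.shape[1]
    spans: list[tuple[int, int]] = []
    if not np.isfinite(config.segment_ptp_max):
        return spans
    for start in range(0, max(1, n - win + 1), step):
        seg = data[:, start:start + win]
        if np.max(seg.max(axis=1) - seg.min(axis=1)) > config.segment_ptp_max:
            if spans and start <= spans[-1][1]:
                spans[-1] = (spans[-1][0], start + win)
            else:
                spans.append((start, start + win))
    return spans


def reject_bad_segments(
    recording: Recording, events: pd.DataFrame, config: PreprocConfig | None = None
) -> tuple[Recording, pd.DataFrame, dict]:
    """Excise high peak-to-peak spans and re-index the event table.

    A sliding window of ``segment_window`` s (step ``segment_step`` s) marks a
    span bad when any channel's peak-to-peak exceeds ``segment_ptp_max`` µV.
    Marked spans are removed from the data; events whose full time-frequency
    epoch (-1.5 to 2.2 s) intersects a bad span are dropped, and the retained
    events' sample indices are shifted by the number of excised samples before
    them. Retained samples are bit-identical to the input.
    """
    config = config or PreprocConfig()
    spans = _bad_spans(recording.data, recording.sfreq, config)
    n = recording.n_samples
    n_bad = sum(b - a for a, b in spans)
    if n_bad > 0.9 * n:
        raise PipelineError(
            f"segment rejection would remove {n_bad}/{n} samples "
            f"({100 * n_bad / n:.0f}%); check data scale or threshold")

    keep = np.ones(n, dtype=bool)
    for a, b in spans:
        keep[a:b] = False
    pre = int(round(-TF_EPOCH[0] * recording.sfreq))
    post = int(round(TF_EPOCH[1] * recording.sfreq))

    onsets = events["onset_sample"].to_numpy()
    drop = np.zeros(len(events), dtype=bool)
    for a, b in spans:
        drop |= (onsets + post > a) & (onsets - pre < b)
    shift = np.cumsum(~keep)  # excised samples at or before each index
    new_events = events.loc[~drop].copy()
    new_onsets = new_events["onset_sample"].to_numpy()
    new_events["onset_sample"] = new_onsets - shift[new_onsets]
    new_events["onset_s"] = new_events["onset_sample"] / recording.sfreq

    out = Recording(recording.data[:, keep], recording.sfreq,
                    list(recording.ch_names), dict(recording.meta))
    log = {"stage": "segment_rejection",
           "spans": [[int(a), int(b)] for a, b in spans],
           "n_samples_removed": int(n_bad),
           "n_events_dropped": int(drop.sum())}
    out.meta.setdefault("log", []).append(log)
    return out, new_events, log


def preprocess(recording: Recording, events: pd.DataFrame,
               config: PreprocConfig | None = None) -> tuple[Recording, pd.DataFrame, dict]:
    """Full cleaning chain: filter -> bad channels -> CAR -> ICA hook -> segments."""
    config = config or PreprocConfig()
    rec = bandpass_filter(recording, config)
    bad = detect_bad_channels(rec, config)
    rec = rereference_car(rec, bad)
    rec = ica_hook(rec)
    rec, events, seg_log = reject_bad_segments(rec, events, config)
    log = {"bad_channels": sorted(bad), **seg_log}
    return rec, events, log
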