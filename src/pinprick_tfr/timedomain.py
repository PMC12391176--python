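"""Time-domain SEP analysis: epoching, trial averaging, peak measurement.

Epochs of -0.5 to 1.5 s around each pinprick are baseline-corrected on
[-0.5, 0) and averaged per hand; the evoked response is summarized by its
negative-positive peak-to-peak amplitude and positive-peak latency at the
central electrode of interest (ipsilesional for stroke, contralateral to the
stimulated dominant hand for controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ParameterError, PipelineError, Recording


@dataclass
class EpochWindowTD:
    start: float = -0.5
    end: float = 1.5
    baseline: tuple[float, float] = (-0.5, 0.0)

    def __post_init__(self) -> None:
        if not self.start < 0 < self.end:
            raise ParameterError("epoch window must straddle 0")
        b0, b1 = self.baseline
        if not (self.start <= b0 < b1 <= 0):
            raise ParameterError("baseline must lie within [start, 0]")


@dataclass
class EpochSet:
    """Time-locked trials: ``data`` is (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    times: np.ndarray  # s, relative to stimulus
    ch_names: list[str]
    hands: np.ndarray  # per-trial hand label
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class SEPMeasurement:
    participant_id: str
    channel: str
    np_amplitude: float  # µV, positive peak minus negative peak
    pos_latency: float  # s
    neg_latency: float  # s
    n_epochs: int
    valid: bool = True


def extract_epochs(recording: Recording, events: pd.DataFrame,
                   window: EpochWindowTD | None = None,
                   baseline_correct: bool = True) -> EpochSet:
    """Cut half-open sample windows [start, end) around each event.

    Each epoch has the mean of its baseline interval subtracted per channel.
    Events whose window would cross a recording edge are skipped and counted
    in ``meta['n_skipped']``.
    """
    window = window or EpochWindowTD()
    sf = recording.sfreq
    i0 = int(round(window.start * sf))
    i1 = int(round(window.end * sf))
    n_samp = i1 - i0
    times = (np.arange(n_samp) + i0) / sf

    trials, hands, skipped = [], [], 0
    for onset, hand in zip(events["onset_sample"], events["hand"]):
        a, b = onset + i0, onset + i1
        if a < 0 or b > recording.n_samples:
            skipped += 1
            continue
        trials.append(recording.data[:, a:b])
        hands.append(hand)
    if not trials:
        raise PipelineError("no events fit inside the recording")
    data = np.stack(trials)
    if baseline_correct:
        bmask = (times >= window.baseline[0]) & (times < window.baseline[1])
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(data, times, list(recording.ch_names), np.array(hands),
                    meta={"n_skipped": skipped, "window": window})


def average_epochs(epochs: EpochSet) -> dict[str, dict]:
    """Pointwise trial mean per hand: ``{hand: {"erp": (ch x t), "n": int}}``."""
    if epochs.n_trials == 0:
        raise PipelineError("cannot average zero epochs")
    out = {}
    for hand in np.unique(epochs.hands):
        sel = epochs.hands == hand
        out[str(hand)] = {"erp": epochs.data[sel].mean(axis=0), "n": int(sel.sum())}
    return out


def measure_sep(erp: np.ndarray, times: np.ndarray, channel: str,
                ch_names: list[str], participant_id: str = "",
                neg_window: tuple[float, float] = (0.05, 0.25),
                pos_window_end: float = 0.5, n_epochs: int = 0) -> SEPMeasurement:
    """Negative-positive peak measurement of one averaged ERP channel.

    The negative peak is the minimum within ``neg_window``; the positive peak
    is the maximum within (negative-peak time, ``pos_window_end``], i.e.
    constrained to follow the negative peak. Amplitude is positive minus
    negative value; latency is the positive peak's time. A flat search window
    is flagged invalid.
    """
    if channel not in ch_names:
        raise ParameterError(f"channel {channel!r} not present")
    x = erp[ch_names.index(channel)]
    nmask = (times >= neg_window[0]) & (times <= neg_window[1])
    if not nmask.any():
        raise ParameterError("negative search window outside epoch")
    seg = x[nmask]
    if np.ptp(x[(times >= neg_window[0]) & (times <= pos_window_end)]) == 0:
        return SEPMeasurement(participant_id, channel, 0.0, np.nan, np.nan,
                              n_epochs, valid=False)
    i_neg = np.argmin(seg)
    t_neg = times[nmask][i_neg]
    v_neg = seg[i_neg]
    pmask = (times > t_neg) & (times <= pos_window_end)
    seg_p = x[pmask]
    i_pos = np.argmax(seg_p)
    t_pos = times[pmask][i_pos]
    v_pos = seg_p[i_pos]
    return SEPMeasurement(participant_id, channel, float(v_pos - v_neg),
                          float(t_pos), float(t_neg), n_epochs)


def select_analysis_channel(group: str, lesion_side: str = "none",
                            dominant_hand: str = "right") -> str:
    """Central electrode entering group statistics.

    Stroke: the ipsilesional central channel (C3 for a left-hemisphere
    lesion, C4 for right), measured for impaired-hand stimulation. Healthy:
    the channel contralateral to the stimulated dominant hand.
    """
    if group in ("motor", "sensorimotor"):
        if lesion_side == "left":
            return "C3"
        if lesion_side == "right":
            return "C4"
        raise PipelineError(f"stroke participant needs a lesion side, got {lesion_side!r}")
    if group == "healthy":
        if dominant_hand == "right":
            return "C3"
        if dominant_hand == "left":
            return "C4"
        raise PipelineError(f"unknown dominant hand {dominant_hand!r}")
    raise PipelineError(f"unknown group {group!r}")


def analysis_hand(group: str, lesion_side: str = "none",
                  dominant_hand: str = "right") -> str:
    """Hand whose stimuli enter the analysis: impaired for stroke, dominant otherwise."""
    if group in ("motor", "sensorimotor"):
        return {"left": "right", "right": "left"}[lesion_side]
    return dominant_hand
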