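"""Core containers and shared constants for the pinprick-SEP pipeline.

Conventions used throughout the package: 0-based sample indexing, half-open
sample windows [start, end), times in seconds internally (milliseconds only in
reports), signals in microvolts (µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default acquisition rate of the pinprick protocol (Hz).
SAMPLING_RATE = 256.0

#: Central electrodes over left / right sensorimotor cortex.
CENTRAL_CHANNELS = ("C3", "C4")

#: Default montage for synthetic recordings (superset of C3/C4).
DEFAULT_CHANNELS = ("C3", "C4", "Cz", "Fz", "Pz", "Oz")

#: The five canonical event-related (de)synchronization windows, as
#: ``label -> (f_lo Hz, f_hi Hz, t_lo s, t_hi s, sign)`` where sign +1 means
#: synchronization (power increase) and -1 desynchronization.
ROI_WINDOWS: dict[str, tuple[float, float, float, float, int]] = {
    "delta_sync": (1.0, 4.0, 0.000, 0.543, +1),
    "theta_sync": (4.0, 6.0, 0.000, 0.262, +1),
    "alpha_desync": (5.0, 13.0, 0.047, 0.785, -1),
    "beta1_desync": (13.0, 27.0, 0.070, 0.566, -1),
    "beta2_resync": (11.0, 17.0, 0.820, 1.601, +1),
}

#: Frequency bands of the underlying physiological modulations the synthetic
#: generator drives, as ``label -> (f_lo Hz, f_hi Hz)``. These are narrower
#: than the measured ROI extents above: an event-related (de)synchronization
#: acts on a rhythm (slow evoked waves, theta, the ~10 Hz mu rhythm, high-
#: beta desynchronization, low-beta rebound), and the wavelet decomposition
#: then smears the modulation out to roughly the windows printed in
#: ``ROI_WINDOWS``.
ROI_MOD_BANDS: dict[str, tuple[float, float]] = {
    "delta_sync": (1.0, 3.5),
    "theta_sync": (4.2, 6.0),
    "alpha_desync": (7.0, 12.5),
    "beta1_desync": (16.0, 26.0),
    "beta2_resync": (12.5, 16.5),
}

#: Short feature names used in feature tables and clinical models.
ROI_FEATURES = ("delta", "theta", "alpha", "beta1", "beta2")

#: Mapping ROI label -> short feature name.
ROI_TO_FEATURE = {
    "delta_sync": "delta",
    "theta_sync": "theta",
    "alpha_desync": "alpha",
    "beta1_desync": "beta1",
    "beta2_resync": "beta2",
}

#: Instrument ranges used to clip generated clinical scores.
SCORE_RANGES = {
    "fma": (0.0, 66.0),
    "emnsa_ext": (0.0, 32.0),
    "emnsa_prop": (0.0, 8.0),
    "sct": (0.0, 54.0),
    "ptt": (0.1, 30.0),
}


class ParameterError(ValueError):
    """Invalid configuration or argument value."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed on the given data."""


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels (10-20 montage labels).
    meta : dict
        Free-form provenance (participant id, stage log, ...).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ParameterError("ch_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def pick(self, name: str) -> np.ndarray:
        """Return one channel's samples (a view)."""
        try:
            idx = self.ch_names.index(name)
        except ValueError:
            raise ParameterError(f"channel {name!r} not in recording") from None
        return self.data[idx]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), ch_names=list(self.ch_names),
                       meta=dict(self.meta))


def contralateral_channel(hand: str) -> str:
    """Central electrode over the hemisphere contralateral to ``hand``."""
    if hand == "left":
        return "C4"
    if hand == "right":
        return "C3"
    raise ParameterError(f"hand must be 'left' or 'right', got {hand!r}")


def participant_rng(master_seed: int, participant_index: int, stream: str) -> np.random.Generator:
    """Named, reproducible per-participant random substream.

    Every source of randomness in the cohort generator derives from the single
    cohort seed through ``SeedSequence(master_seed, participant_index,
    hash(stream))`` so that any participant can be regenerated in isolation.
    """
    key = int.from_bytes(stream.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), participant_index, key]))
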