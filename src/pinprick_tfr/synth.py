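"""Synthetic pinprick-EEG cohorts with known ground truth.

Emulates the study protocol this package analyzes: 160 pinprick stimuli per
hand (10 sets of 8 skin compartments, the whole block run twice, hands
alternating set by set), 256 Hz EEG with a 1/f background, a biphasic
somatosensory evoked potential on the central electrode contralateral to the
stimulated hand, and five event-related band-power modulations
(delta/theta synchronization, alpha/beta desynchronization, beta
resynchronization). Clinical scores are generated as linear functions of the
injected EEG effect magnitudes plus Gaussian noise, then clipped to the
instrument ranges, so that every downstream stage of the pipeline has a
recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    DEFAULT_CHANNELS,
    ROI_FEATURES,
    ROI_MOD_BANDS,
    ROI_WINDOWS,
    SAMPLING_RATE,
    SCORE_RANGES,
    ParameterError,
    Recording,
    contralateral_channel,
    participant_rng,
)

# --------------------------------------------------------------------------
# Stimulus protocol
# --------------------------------------------------------------------------


@dataclass
class StimulusProtocol:
    """Pinprick stimulation schedule.

    ``n_sets`` sets of one stimulus per skin compartment are applied to each
    hand, hands alternating set by set, and the whole procedure is repeated
    ``n_rounds`` times: 10 x 8 x 2 = 160 stimuli per hand at the defaults.
    The inter-stimulus interval is ``isi_mean`` with uniform jitter of
    ``+- isi_jitter`` seconds.
    """

    n_sets: int = 10
    n_compartments: int = 8
    n_rounds: int = 2
    isi_mean: float = 3.0
    isi_jitter: float = 0.5
    hands: tuple[str, str] = ("left", "right")
    lead_in: float = 5.0

    @property
    def events_per_hand(self) -> int:
        return self.n_sets * self.n_compartments * self.n_rounds


def generate_protocol(
    protocol: StimulusProtocol,
    seed: int | np.random.Generator,
    sfreq: float = SAMPLING_RATE,
) -> pd.DataFrame:
    """Draw one stimulation schedule.

    Returns a table with one row per stimulus: ``onset_s``, ``onset_sample``
    (onsets are snapped to the sample grid), ``hand``, ``compartment``
    (0-based), ``set_index`` and ``round``. Compartment order is randomized
    within each set; hands alternate set by set; onset times are strictly
    increasing.
    """
    if min(protocol.n_sets, protocol.n_compartments, protocol.n_rounds) < 1:
        raise ParameterError("protocol counts must be >= 1")
    if protocol.isi_mean - protocol.isi_jitter <= 0:
        raise ParameterError("inter-stimulus interval must stay positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    t = protocol.lead_in
    for rnd in range(protocol.n_rounds):
        for s in range(protocol.n_sets):
            for hand in protocol.hands:
                order = rng.permutation(protocol.n_compartments)
                for comp in order:
                    rows.append((t, hand, int(comp), s, rnd))
                    t += protocol.isi_mean + rng.uniform(-protocol.isi_jitter, protocol.isi_jitter)
    df = pd.DataFrame(rows, columns=["onset_s", "hand", "compartment", "set_index", "round"])
    df["onset_sample"] = np.round(df["onset_s"] * sfreq).astype(int)
    df["onset_s"] = df["onset_sample"] / sfreq
    return df[["onset_sample", "onset_s", "hand", "compartment", "set_index", "round"]]


# --------------------------------------------------------------------------
# Subject and cohort specifications
# --------------------------------------------------------------------------

#: Group-level distributions for the injected effects. SEP amplitude (µV) and
#: positive-peak latency (s) means/SDs follow the group statistics this
#: pipeline is designed to detect; ROI gains are event-related power
#: modulation depths in dB of band amplitude (+ = synchronization), on the
#: scale of the per-feature power distributions the study reports (roughly
#: -2 to +2 dB across participants), with the alpha desynchronization
#: attenuated in the sensorimotor group.
GROUP_PARAMS: dict[str, dict] = {
    "healthy": {
        "amp": (2.81, 1.30),
        "lat": (0.20269, 0.07062),
        "gains_db": {"delta": 1.8, "theta": 1.5, "alpha": -1.8, "beta1": -1.5, "beta2": 1.4},
    },
    "motor": {
        "amp": (3.22, 2.68),
        "lat": (0.16909, 0.07605),
        "gains_db": {"delta": 1.8, "theta": 1.5, "alpha": -1.6, "beta1": -1.0, "beta2": 0.8},
    },
    "sensorimotor": {
        "amp": (1.36, 0.54),
        "lat": (0.16146, 0.06663),
        "gains_db": {"delta": 1.4, "theta": 1.2, "alpha": -0.9, "beta1": -1.0, "beta2": 0.6},
    },
}

#: Between-subject SD of each ROI gain, in dB.
GAIN_SUBJECT_SD_DB = 0.75

#: Clip bounds keeping injected SEPs measurable: amplitude >= 0.3 µV,
#: positive-peak latency inside the peak-search window.
AMP_MIN = 0.3
LAT_CLIP = (0.12, 0.40)

#: Default linear clinical-score models: score = intercept + sum(coef * x)
#: + N(0, noise_sd), clipped to the instrument range. Predictors are the
#: injected per-subject EEG magnitudes (amplitude in µV, ROI gains in dB) and
#: ``stroke_type`` coded sensorimotor = 1, motor = 0; ``"x:stroke_type"``
#: denotes an interaction. Effect directions mirror the associations the
#: statistical stage is built to detect (beta1 desynchronization -> motor
#: score; beta2/delta -> somatosensory score; amplitude x type -> touch
#: threshold and somatosensory change).
DEFAULT_CLINICAL_MODELS: dict[str, dict] = {
    "fma_t1": {"intercept": 30.0, "beta1": -19.0, "noise_sd": 15.0, "range": "fma"},
    "emnsa_t1": {
        "intercept": 29.0, "beta2": 2.58, "stroke_type": -8.0,
        "delta:stroke_type": 5.0, "noise_sd": 1.5, "range": "emnsa_ext",
    },
    "ptt_t1": {
        "intercept": 2.5, "stroke_type": 5.0, "amplitude": 0.4,
        "amplitude:stroke_type": -0.9, "noise_sd": 0.8, "range": "ptt",
    },
    "fma_change": {"intercept": 8.0, "beta2": -4.0, "noise_sd": 2.0},
    "emnsa_change": {"intercept": 1.0, "amplitude:stroke_type": 2.5, "noise_sd": 1.0},
    "ptt_change": {"intercept": -0.5, "stroke_type": -3.0, "noise_sd": 1.0},
}


@dataclass
class SubjectSpec:
    """Ground-truth parameters of one synthetic participant."""

    participant_id: str
    group: str  # healthy | motor | sensorimotor
    lesion_side: str  # left | right | none
    erp_np_amplitude: float  # µV, negative-to-positive excursion
    erp_pos_latency: float  # s
    roi_gains: dict[str, float] = field(default_factory=dict)  # ROI label -> amplitude gain

    def __post_init__(self) -> None:
        if self.erp_np_amplitude < 0:
            raise ParameterError("erp_np_amplitude must be >= 0")
        for label, g in self.roi_gains.items():
            if g <= 0:
                raise ParameterError(f"gain for {label} must be > 0")

    @property
    def impaired_hand(self) -> str:
        """Hand analyzed downstream: contralesional for stroke, dominant (right) otherwise."""
        if self.lesion_side == "left":
            return "right"
        if self.lesion_side == "right":
            return "left"
        return "right"

    @property
    def gains_db(self) -> dict[str, float]:
        return {k: 20.0 * np.log10(v) for k, v in self.roi_gains.items()}


@dataclass
class CohortSpec:
    """Study-level configuration of a synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"healthy": 10, "motor": 6, "sensorimotor": 10})
    sampling_rate: float = SAMPLING_RATE
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    background_exponent: float = 1.0
    background_rms: float = 10.0  # µV per channel
    channel_corr: float = 0.5  # shared-source fraction emulating volume conduction
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    clinical_models: dict = field(default_factory=lambda: DEFAULT_CLINICAL_MODELS)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ParameterError("group sizes must be positive")
        if self.sampling_rate <= 2 * 35.0:
            raise ParameterError("sampling rate must exceed twice the top analysis frequency")
        missing = {"C3", "C4"} - set(self.channels)
        if missing:
            raise ParameterError(f"channels must include C3 and C4 (missing {missing})")


# --------------------------------------------------------------------------
# Signal synthesis
# --------------------------------------------------------------------------


def simulate_background(
    cohort: CohortSpec, duration: float, seed: int | np.random.Generator
) -> Recording:
    """1/f^exponent Gaussian background EEG, independent across participants.

    Spectral shaping is done in the frequency domain (amplitude scaled by
    f^(-exponent/2)), the DC bin is zeroed, and each channel is rescaled to
    ``cohort.background_rms`` µV RMS. Channels share a common 1/f source with
    weight ``channel_corr`` (volume conduction makes scalp channels strongly
    correlated, which the bad-channel correlation criterion relies on).
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * cohort.sampling_rate))
    white = rng.standard_normal((len(cohort.channels) + 1, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / cohort.sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-cohort.background_exponent / 2.0)
    data = np.fft.irfft(spec * shape, n=n, axis=1)
    c = cohort.channel_corr
    if not 0 <= c < 1:
        raise ParameterError("channel_corr must be in [0, 1)")
    data = np.sqrt(1.0 - c) * data[1:] + np.sqrt(c) * data[:1]
    rms = np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    data *= cohort.background_rms / rms
    return Recording(data, cohort.sampling_rate, list(cohort.channels))


def _erp_template(amplitude: float, latency: float, sfreq: float,
                  neg_frac: float = 0.6, sigma_neg: float = 0.025,
                  sigma_pos: float = 0.040, neg_rel: float = 0.8):
    """Biphasic SEP template sampled on the recording grid.

    A difference of two Gaussian lobes (negative lobe peaking near
    ``neg_frac * latency``, then a positive lobe). The template is rescaled
    and time-shifted numerically so that its noise-free negative-to-positive
    excursion equals ``amplitude`` exactly and its positive peak sits at
    ``latency`` on a 32x oversampled grid.

    Returns ``(samples, waveform)`` where ``samples`` are offsets (in samples)
    from the stimulus and ``waveform`` is in µV.
    """
    t_pos = latency
    t_neg = neg_frac * latency

    def shape(t):
        return (np.exp(-((t - t_pos) ** 2) / (2 * sigma_pos**2))
                - neg_rel * np.exp(-((t - t_neg) ** 2) / (2 * sigma_neg**2)))

    fine = np.arange(-0.1, latency + 6 * sigma_pos, 1.0 / (32 * sfreq))
    u = shape(fine)
    scale = amplitude / (u.max() - u.min())
    delta = latency - fine[np.argmax(u)]  # correct peak pull from lobe overlap

    n_before = int(round(0.05 * sfreq))
    n_after = int(round((latency + 5 * sigma_pos) * sfreq))
    samples = np.arange(-n_before, n_after + 1)
    wave = scale * shape(samples / sfreq - delta)
    return samples, wave


def inject_erp(recording: Recording, events: pd.DataFrame, subject: SubjectSpec) -> Recording:
    """Add the subject's biphasic evoked response at every stimulus.

    The waveform is added on the central channel contralateral to the
    stimulated hand; injection is linear (superposition holds when epochs do
    not overlap). Returns a new Recording.
    """
    if not 0 < subject.erp_pos_latency <= 0.5:
        raise ParameterError("positive-peak latency must be in (0, 500] ms")
    out = recording.copy()
    if subject.erp_np_amplitude == 0:
        return out
    samples, wave = _erp_template(subject.erp_np_amplitude, subject.erp_pos_latency,
                                  recording.sfreq)
    for hand in ("left", "right"):
        ch = out.pick(contralateral_channel(hand))
        for onset in events.loc[events["hand"] == hand, "onset_sample"].to_numpy():
            idx = onset + samples
            ok = (idx >= 0) & (idx < out.n_samples)
            ch[idx[ok]] += wave[ok]
    return out


def _band_component(x: np.ndarray, f_lo: float, f_hi: float, sfreq: float) -> np.ndarray:
    """Zero-phase band-pass component of one channel (linear-phase FIR, 'same')."""
    numtaps = 2 * int(round(3 * sfreq / f_lo)) + 1
    h = signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=sfreq)
    return signal.fftconvolve(x, h, mode="same")


def _event_taper(n_samples: int, onsets: np.ndarray, t_lo: float, t_hi: float,
                 sfreq: float, shape: str = "tukey", ramp: float = 0.05) -> np.ndarray:
    """Per-sample modulation envelope over each event's [t_lo, t_hi] window.

    ``"tukey"`` (default): full modulation depth over the central half of the
    window with raised-cosine rise/fall over the outer quarters — event-
    related power modulations wax and wane smoothly rather than switching on
    and off. ``"hann"``: a raised-cosine bump peaking at the window center.
    ``"flat"``: unit plateau with short raised-cosine ramps just outside the
    window edges (useful when a constant modulation depth across the whole
    window is wanted, e.g. for calibration checks).
    """
    if shape == "hann":
        win_len = int(round((t_hi - t_lo) * sfreq))
        taper = np.sin(np.pi * np.arange(win_len) / max(win_len - 1, 1)) ** 2
        start_off = int(round(t_lo * sfreq))
    elif shape == "tukey":
        win_len = int(round((t_hi - t_lo) * sfreq))
        taper = signal.windows.tukey(win_len, alpha=0.5)
        start_off = int(round(t_lo * sfreq))
    elif shape == "flat":
        win_len = int(round((t_hi - t_lo + 2 * ramp) * sfreq))
        taper = np.ones(win_len)
        n_ramp = int(round(ramp * sfreq))
        if n_ramp > 0:
            up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            taper[:n_ramp] = up
            taper[-n_ramp:] = up[::-1]
        start_off = int(round((t_lo - ramp) * sfreq))
    else:
        raise ParameterError(f"unknown envelope shape {shape!r}")
    env = np.zeros(n_samples)
    for onset in onsets:
        i0 = onset + start_off
        idx = np.arange(i0, i0 + win_len)
        ok = (idx >= 0) & (idx < n_samples)
        env[idx[ok]] = np.maximum(env[idx[ok]], taper[ok])
    return env


def inject_oscillations(recording: Recording, events: pd.DataFrame,
                        subject: SubjectSpec, envelope: str = "tukey") -> Recording:
    """Apply the subject's event-related band-power modulations.

    For each of the five canonical time-frequency windows with gain g != 1,
    the band-limited component of the target channel (contralateral to the
    stimulated hand) is scaled inside the post-stimulus window following a
    smooth time course: the channel receives ``(g - 1) * envelope *
    band_component``, with the envelope a raised-cosine bump over the window
    by default (see ``_event_taper``). The band that is modulated is the
    physiological rhythm band of that phenomenon (``ROI_MOD_BANDS``); the
    ROI's printed time-frequency window is what the decomposition measures
    after spectral/temporal smearing. Gains > 1 produce synchronization,
    < 1 desynchronization; in trial-averaged dB power the injected depth at
    the envelope peak is 20*log10(g) inside the modulated band.
    """
    for label, g in subject.roi_gains.items():
        if label not in ROI_WINDOWS:
            raise ParameterError(f"unknown ROI label {label!r}")
        if g <= 0:
            raise ParameterError(f"gain for {label} must be > 0")
    out = recording.copy()
    for hand in ("left", "right"):
        onsets = events.loc[events["hand"] == hand, "onset_sample"].to_numpy()
        if onsets.size == 0:
            continue
        ch = out.pick(contralateral_channel(hand))
        base = ch.copy()
        for label, g in subject.roi_gains.items():
            if g == 1.0:
                continue
            _, _, t_lo, t_hi, _sign = ROI_WINDOWS[label]
            f_lo, f_hi = ROI_MOD_BANDS[label]
            band = _band_component(base, f_lo, f_hi, recording.sfreq)
            env = _event_taper(out.n_samples, onsets, t_lo, t_hi,
                               recording.sfreq, shape=envelope)
            ch += (g - 1.0) * env * band
    return out


# --------------------------------------------------------------------------
# Clinical scores
# --------------------------------------------------------------------------


def _model_predictors(row: pd.Series) -> dict[str, float]:
    st = 1.0 if row["group"] == "sensorimotor" else 0.0
    x = {"stroke_type": st, "amplitude": row["amplitude"]}
    for f in ROI_FEATURES:
        x[f] = row[f]
    for k in list(x):
        if k != "stroke_type":
            x[f"{k}:stroke_type"] = x[k] * st
    return x


def generate_clinical_scores(truth: pd.DataFrame, models: dict,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Clinical tables at T1 and T2 from injected EEG magnitudes.

    ``truth`` has one row per participant with columns ``participant``,
    ``group``, ``amplitude`` and the five ROI dB magnitudes. Scores are linear
    in these predictors plus Gaussian noise and clipped to instrument ranges;
    T2 = T1 + a generated change. Healthy participants get NaN (the
    instruments are administered in the stroke cohort only).
    """
    rows = []
    for _, r in truth.iterrows():
        rec = {"participant": r["participant"], "group": r["group"],
               "lesion_side": r["lesion_side"]}
        if r["group"] == "healthy":
            for s in ("fma", "emnsa", "ptt"):
                rec[f"{s}_t1"] = np.nan
                rec[f"{s}_t2"] = np.nan
            rows.append(rec)
            continue
        x = _model_predictors(r)
        for score in ("fma", "emnsa", "ptt"):
            m = models[f"{score}_t1"]
            val = m.get("intercept", 0.0) + sum(
                coef * x[name] for name, coef in m.items()
                if name not in ("intercept", "noise_sd", "range"))
            val += rng.normal(0.0, m.get("noise_sd", 0.0))
            lo, hi = SCORE_RANGES[m.get("range", "fma" if score == "fma" else
                                        "emnsa_ext" if score == "emnsa" else "ptt")]
            t1 = float(np.clip(val, lo, hi))
            mc = models[f"{score}_change"]
            change = mc.get("intercept", 0.0) + sum(
                coef * x[name] for name, coef in mc.items()
                if name not in ("intercept", "noise_sd", "range"))
            change += rng.normal(0.0, mc.get("noise_sd", 0.0))
            rec[f"{score}_t1"] = t1
            rec[f"{score}_t2"] = float(np.clip(t1 + change, lo, hi))
        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

_LESION_LEFT = {"motor": 4 / 6, "sensorimotor": 8 / 10}


def draw_subjects(cohort: CohortSpec) -> list[SubjectSpec]:
    """Sample every participant's ground-truth parameters (no signals yet)."""
    subjects = []
    idx = 0
    for group in ("healthy", "motor", "sensorimotor"):
        n = cohort.group_sizes.get(group, 0)
        n_left = 0 if group == "healthy" else int(round(_LESION_LEFT[group] * n))
        for j in range(n):
            rng = participant_rng(cohort.seed, idx, "subject")
            p = GROUP_PARAMS[group]
            amp = max(AMP_MIN, rng.normal(*p["amp"]))
            lat = float(np.clip(rng.normal(*p["lat"]), *LAT_CLIP))
            gains = {}
            for label, feat in zip(ROI_WINDOWS, ROI_FEATURES):
                db = rng.normal(p["gains_db"][feat], GAIN_SUBJECT_SD_DB)
                gains[label] = float(10.0 ** (db / 20.0))
            side = "none" if group == "healthy" else ("left" if j < n_left else "right")
            subjects.append(SubjectSpec(
                participant_id=f"sub-{idx:02d}", group=group, lesion_side=side,
                erp_np_amplitude=float(amp), erp_pos_latency=float(lat),
                roi_gains=gains))
            idx += 1
    return subjects


def ground_truth_table(subjects: list[SubjectSpec]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"participant": s.participant_id, "group": s.group,
               "lesion_side": s.lesion_side, "amplitude": s.erp_np_amplitude,
               "latency": s.erp_pos_latency}
        db = s.gains_db
        for label, feat in zip(ROI_WINDOWS, ROI_FEATURES):
            row[feat] = db[label]
        rows.append(row)
    return pd.DataFrame(rows)


def synthesize_participant(cohort: CohortSpec, subject: SubjectSpec,
                           participant_index: int) -> tuple[pd.DataFrame, Recording]:
    """Protocol + background + ERP + oscillations for one participant."""
    rng_prot = participant_rng(cohort.seed, participant_index, "protocol")
    events = generate_protocol(cohort.protocol, rng_prot, cohort.sampling_rate)
    duration = float(events["onset_s"].iloc[-1]) + 3.0
    rng_bg = participant_rng(cohort.seed, participant_index, "background")
    rec = simulate_background(cohort, duration, rng_bg)
    rec = inject_erp(rec, events, subject)
    rec = inject_oscillations(rec, events, subject)
    rec.meta.update(participant=subject.participant_id, group=subject.group,
                    lesion_side=subject.lesion_side, seed=cohort.seed,
                    participant_index=participant_index)
    return events, rec


def generate_cohort(cohort: CohortSpec, recordings: bool = True) -> dict:
    """Full synthetic cohort.

    Returns a dict with ``subjects`` (SubjectSpec list), ``truth`` (injected
    magnitudes per participant), ``clinical`` (T1/T2 scores), and — when
    ``recordings`` is true — ``events`` and ``recordings`` keyed by
    participant id. Identical seeds give byte-identical tables.
    """
    subjects = draw_subjects(cohort)
    truth = ground_truth_table(subjects)
    rng_clin = np.random.default_rng(np.random.SeedSequence([cohort.seed, 987654321]))
    clinical = generate_clinical_scores(truth, cohort.clinical_models, rng_clin)
    out = {"subjects": subjects, "truth": truth, "clinical": clinical}
    if recordings:
        out["events"] = {}
        out["recordings"] = {}
        for i, s in enumerate(subjects):
            ev, rec = synthesize_participant(cohort, s, i)
            out["events"][s.participant_id] = ev
            out["recordings"][s.participant_id] = rec
    return out


def generate_feature_table(n_motor: int, n_sensorimotor: int, seed: int,
                           models: dict | None = None) -> dict:
    """Stroke-only feature table for clinical-regression experiments.

    Samples per-subject EEG magnitudes from the stroke group distributions and
    generates clinical scores from ``models`` (defaults to the cohort models).
    Returns ``{"features": DataFrame, "truth": DataFrame}`` where ``features``
    is ready for the clinical regression stage (wide form: amplitude, the five
    ROI dB powers, stroke_type, scores at T1/T2).
    """
    models = DEFAULT_CLINICAL_MODELS if models is None else models
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_motor + n_sensorimotor):
        group = "motor" if i < n_motor else "sensorimotor"
        p = GROUP_PARAMS[group]
        row = {"participant": f"sub-{i:03d}", "group": group,
               "lesion_side": "left",
               "amplitude": max(AMP_MIN, rng.normal(*p["amp"]))}
        for feat in ROI_FEATURES:
            row[feat] = rng.normal(p["gains_db"][feat], GAIN_SUBJECT_SD_DB)
        rows.append(row)
    truth = pd.DataFrame(rows)
    clinical = generate_clinical_scores(truth, models, rng)
    features = truth.merge(
        clinical.drop(columns=["group", "lesion_side"]), on="participant")
    features["stroke_type"] = features["group"]
    return {"features": features, "truth": truth}
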