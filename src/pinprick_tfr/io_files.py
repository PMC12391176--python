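"""File formats: EDF recordings, event/clinical tables, configs, results.

Recordings are exchanged as plain EDF (European Data Format): written by the
minimal 16-bit writer below (one data record per second, final partial
record zero-padded) and read back through ``mne.io.read_raw_edf``, which
doubles as an independent check of the writer. Events travel as TSV
(onset_sample, onset_s, hand, compartment), clinical scores as CSV, ground
truth and model results as JSON, configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ParameterError, Recording

EVENT_COLUMNS = ["onset_sample", "onset_s", "hand", "compartment"]


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_recording(path: str | Path, recording: Recording) -> Path:
    """Write a Recording as plain EDF (16-bit, 1-second data records).

    Physical units are µV; each channel gets a symmetric physical range
    covering its data, so quantization error is range/65534. The sampling
    rate must be an integer (samples per 1 s record). The final partial
    record is zero-padded.
    """
    path = Path(path)
    sfreq = recording.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))

    data = np.zeros((n_ch, n_records * spr))
    data[:, :recording.n_samples] = recording.data
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)

    header = b"".join([
        _pad("0", 8),
        _pad(str(recording.meta.get("participant", "X X X X")), 80),
        _pad("Startdate 01-JAN-2000", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(name, 16) for name in recording.ch_names],          # label
        [_pad("", 80)] * n_ch,                                    # transducer
        [_pad("uV", 8)] * n_ch,                                   # dimension
        [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max],             # phys min
        [_pad(f"{m:.6g}"[:8], 8) for m in phys_max],              # phys max
        [_pad("-32767", 8)] * n_ch,                               # dig min
        [_pad("32767", 8)] * n_ch,                                # dig max
        [_pad("", 80)] * n_ch,                                    # prefiltering
        [_pad(str(spr), 8)] * n_ch,                               # samples/record
        [_pad("", 32)] * n_ch,                                    # reserved
    ]
    header += b"".join(b"".join(col) for col in fields)

    # physical values re-derived from the printed (truncated) header numbers,
    # so the round trip matches what any standard reader reconstructs
    pmax = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    digital = np.clip(np.round(data / pmax[:, None] * 32767), -32767, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_recording(path: str | Path, events_path: str | Path | None = None,
                   expect_sfreq: float | None = None):
    """Read an EDF recording (µV) and, when given, its events TSV.

    Validates the presence of C3/C4 and, when ``expect_sfreq`` is set,
    refuses a mismatching sampling rate rather than resampling. Returns
    ``Recording`` or ``(Recording, events)``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> µV
    ch_names = list(raw.ch_names)
    missing = {"C3", "C4"} - set(ch_names)
    if missing:
        raise ParameterError(f"recording lacks required channels {sorted(missing)}")
    sfreq = float(raw.info["sfreq"])
    if expect_sfreq is not None and abs(sfreq - expect_sfreq) > 1e-6:
        raise ParameterError(
            f"sampling rate {sfreq} Hz != configured {expect_sfreq} Hz; "
            "resample the file explicitly before running the pipeline")
    rec = Recording(data, sfreq, ch_names, {"source": str(path)})
    if events_path is None:
        return rec
    events_path = Path(events_path)
    if not events_path.exists():
        raise FileNotFoundError(
            f"expected events table at {events_path} alongside {path}")
    return rec, read_events(events_path)


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def write_events(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    cols = [c for c in EVENT_COLUMNS if c in events.columns] + \
        [c for c in events.columns if c not in EVENT_COLUMNS]
    events[cols].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ParameterError(f"events table missing columns {sorted(missing)}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=1, default=default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable configuration of an end-to-end run.

    Every numeric constant of the analysis lives in exactly one default
    here or in the stage dataclasses it instantiates.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: {"healthy": 10, "motor": 6,
                                                       "sensorimotor": 10})
    sampling_rate: float = 256.0
    channels: list = field(default_factory=lambda: ["C3", "C4", "Cz", "Fz", "Pz", "Oz"])
    background_exponent: float = 1.0
    background_rms: float = 10.0
    band: list = field(default_factory=lambda: [1.0, 35.0])
    segment_ptp_max: float = 200.0
    n_iterations: int = 2000
    percentile: float = 95.0
    two_sided: bool = True
    min_roi_bins: int = 10

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
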