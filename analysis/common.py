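"""Shared driver helpers: one cohort run, cached between analysis steps.

The numbered scripts form one narrative over a single synthetic cohort
(seed 1 by default, override with PINPRICK_SEED). Step 02 computes the
expensive per-participant stages and caches them under results/cache/; later
steps load the cache or tell you to run step 02 first.
"""

from __future__ import annotations

import os
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
CACHE = RESULTS / "cache"
SEED = int(os.environ.get("PINPRICK_SEED", "1"))


def run_config():
    from pinprick_tfr.io_files import RunConfig

    return RunConfig(seed=SEED, out_dir=str(RESULTS / "pipeline"))


def compute_cohort_features(progress=True):
    """Synthesize + preprocess + SEP + TFR for the default 26-person cohort."""
    from pinprick_tfr.pipeline import cohort_from_config, participant_features
    from pinprick_tfr.synth import (draw_subjects, generate_clinical_scores,
                                    ground_truth_table, synthesize_participant)

    cfg = run_config()
    cohort = cohort_from_config(cfg)
    subjects = draw_subjects(cohort)
    truth = ground_truth_table(subjects)
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 987654321]))
    clinical = generate_clinical_scores(truth, cohort.clinical_models, rng)
    seps, tfrs = [], []
    for i, s in enumerate(subjects):
        if progress:
            print(f"  {s.participant_id} ({s.group})", file=sys.stderr)
        ev, rec = synthesize_participant(cohort, s, i)
        sep, tfr, _ = participant_features(rec, ev, s, cfg)
        seps.append({"participant": s.participant_id, "group": s.group,
                     "np_amplitude": sep.np_amplitude,
                     "pos_latency_ms": 1e3 * sep.pos_latency,
                     "n_epochs": sep.n_epochs})
        tfrs.append(tfr)
    return {"config": cfg, "truth": truth, "clinical": clinical,
            "sep_table": pd.DataFrame(seps), "tfrs": tfrs}


def save_cache(data) -> None:
    CACHE.mkdir(parents=True, exist_ok=True)
    data["sep_table"].to_csv(CACHE / "sep_table.csv", index=False)
    data["truth"].to_csv(CACHE / "truth.csv", index=False)
    data["clinical"].to_csv(CACHE / "clinical.csv", index=False)
    t0 = data["tfrs"][0]
    np.savez(CACHE / "tfr_stack.npz",
             stack=np.stack([t.values for t in data["tfrs"]]),
             freqs=t0.freqs, times=t0.times,
             participants=np.array([t.labels["participant"] for t in data["tfrs"]]),
             seed=SEED)


def load_cache():
    from pinprick_tfr.timefreq import TFRMatrix

    path = CACHE / "tfr_stack.npz"
    if not path.exists():
        sys.exit("cache missing - run analysis/02_preprocess_and_sep.py first")
    z = np.load(path, allow_pickle=False)
    if int(z["seed"]) != SEED:
        sys.exit("cache was built with a different PINPRICK_SEED - rerun step 02")
    tfrs = [TFRMatrix(v, z["freqs"], z["times"], "dB", {"participant": str(p)})
            for v, p in zip(z["stack"], z["participants"])]
    return {"sep_table": pd.read_csv(CACHE / "sep_table.csv"),
            "truth": pd.read_csv(CACHE / "truth.csv"),
            "clinical": pd.read_csv(CACHE / "clinical.csv"),
            "tfrs": tfrs}
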