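"""End-to-end orchestration: simulate -> preprocess -> SEP -> TFR -> mask ->
features -> statistics.

Each stage is a thin call into the corresponding module; the pipeline
threads the per-participant condition assignment (stroke: ipsilesional
channel, impaired-hand stimuli; healthy: contralateral channel per
stimulated hand, conditions averaged) and carries the run seed and config
hash into every output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import masking, stats, timedomain, timefreq
from .core import ROI_TO_FEATURE, PipelineError
from .io_files import RunConfig, write_json, write_table
from .preprocess import PreprocConfig, preprocess
from .synth import (CohortSpec, StimulusProtocol, draw_subjects,
                    generate_clinical_scores, ground_truth_table,
                    synthesize_participant)


def cohort_from_config(config: RunConfig) -> CohortSpec:
    return CohortSpec(
        group_sizes=dict(config.group_sizes),
        sampling_rate=config.sampling_rate,
        channels=tuple(config.channels),
        background_exponent=config.background_exponent,
        background_rms=config.background_rms,
        protocol=StimulusProtocol(),
        seed=config.seed,
    )


def participant_features(rec, events, subject, config: RunConfig):
    """Preprocess one participant and return SEP measurement + dB TFR.

    The TFR entering the cohort mask: stroke participants contribute the
    ipsilesional channel during impaired-hand stimulation; healthy
    participants contribute the average of both contralateral-channel
    conditions.
    """
    pcfg = PreprocConfig(band=tuple(config.band), segment_ptp_max=config.segment_ptp_max)
    rec, events, log = preprocess(rec, events, pcfg)

    channel = timedomain.select_analysis_channel(subject.group, subject.lesion_side)
    hand = timedomain.analysis_hand(subject.group, subject.lesion_side)
    epochs = timedomain.extract_epochs(rec, events)
    averages = timedomain.average_epochs(epochs)
    if hand not in averages:
        raise PipelineError(f"no epochs for analysis hand {hand!r}")
    sep = timedomain.measure_sep(
        averages[hand]["erp"], epochs.times, channel, epochs.ch_names,
        participant_id=subject.participant_id, n_epochs=averages[hand]["n"])

    if subject.group == "healthy":
        t_left = timefreq.epoch_tfr(rec, events, "left", "C4")
        t_right = timefreq.epoch_tfr(rec, events, "right", "C3")
        tfr = timefreq.TFRMatrix((t_left.values + t_right.values) / 2.0,
                                 t_left.freqs, t_left.times, "dB",
                                 {"participant": subject.participant_id,
                                  "condition": "both-hands"},
                                 t_left.edge_samples)
    else:
        tfr = timefreq.epoch_tfr(rec, events, hand, channel,
                                 labels={"participant": subject.participant_id,
                                         "condition": f"{hand}-hand"})
    return sep, tfr, log


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full synthetic-cohort analysis.

    Returns a dict with the SEP table, the mask/ROIs, the feature table and
    every fitted model; optionally writes CSV/JSON outputs (all stamped with
    the config hash and seed) under ``config.out_dir``.
    """
    cohort = cohort_from_config(config)
    subjects = draw_subjects(cohort)
    truth = ground_truth_table(subjects)
    rng_clin = np.random.default_rng(np.random.SeedSequence([cohort.seed, 987654321]))
    clinical = generate_clinical_scores(truth, cohort.clinical_models, rng_clin)

    seps, tfrs, logs = [], [], []
    for i, subject in enumerate(subjects):
        events, rec = synthesize_participant(cohort, subject, i)
        sep, tfr, log = participant_features(rec, events, subject, config)
        seps.append({"participant": subject.participant_id, "group": subject.group,
                     "channel": sep.channel, "np_amplitude": sep.np_amplitude,
                     "pos_latency_ms": 1e3 * sep.pos_latency, "n_epochs": sep.n_epochs,
                     "valid": sep.valid})
        tfrs.append(tfr)
        logs.append({"participant": subject.participant_id, **log})
    sep_table = pd.DataFrame(seps)

    mcfg = masking.MaskConfig(n_iterations=config.n_iterations,
                              percentile=config.percentile,
                              two_sided=config.two_sided,
                              min_roi_bins=config.min_roi_bins)
    disc = masking.discover_rois(tfrs, mcfg, seed=config.seed)

    rows = []
    for tfr in tfrs:
        powers = masking.extract_roi_power(tfr, disc["rois"])
        rows.append({"participant": tfr.labels["participant"], **powers})
    roi_table = pd.DataFrame(rows)
    features = sep_table.merge(roi_table, on="participant").merge(
        clinical.drop(columns=["group"]), on="participant")
    features = features.rename(columns={
        roi: feat for roi, feat in ROI_TO_FEATURE.items() if roi in features})

    models: dict[str, stats.ModelResult] = {}
    models["anova_amplitude"] = stats.anova_amplitude(features)
    long = features.melt(
        id_vars=["participant", "group"],
        value_vars=[f for f in ("delta", "theta", "alpha", "beta1", "beta2")
                    if f in features],
        var_name="feature", value_name="power")
    models["mixed_model_power"] = stats.mixed_model_power(long)
    have_features = all(f in features for f in ("delta", "theta", "alpha", "beta1", "beta2"))
    if have_features:
        for outcome in ("fma", "emnsa", "ptt"):
            for change in (False, True):
                key = f"{outcome}_{'change' if change else 't1'}"
                try:
                    models[key] = stats.clinical_regression(features, outcome, change)
                except Exception as exc:  # small cohorts can defeat the full model
                    models[key] = None
                    logs.append({"stage": "stats", "model": key, "error": str(exc)})

    result = {"config": config, "truth": truth, "clinical": clinical,
              "sep_table": sep_table, "features": features, "mask": disc["mask"],
              "rois": disc["rois"], "tmap": disc["tmap"], "freqs": disc["freqs"],
              "times": disc["times"], "models": models, "logs": logs,
              "n_null": disc["n_null"]}
    if write:
        _write_outputs(result)
    return result


def _write_outputs(result: dict) -> None:
    config: RunConfig = result["config"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    write_table(out / "sep_measurements.csv", result["sep_table"])
    write_table(out / "features.csv", result["features"])
    write_table(out / "clinical.csv", result["clinical"])
    write_table(out / "ground_truth.csv", result["truth"])
    write_json(out / "mask.json", {
        **stamp,
        "freqs_hz": result["freqs"],
        "times_s": result["times"],
        "mask": result["mask"].astype(int),
        "n_null_per_bin": result["n_null"]})
    write_json(out / "rois.json", {
        **stamp,
        "rois": [{"label": r.label, "sign": r.sign,
                  "f_lo_hz": r.f_lo, "f_hi_hz": r.f_hi,
                  "t_lo_ms": 1e3 * r.t_lo, "t_hi_ms": 1e3 * r.t_hi,
                  "n_bins": r.n_bins} for r in result["rois"]]})
    summaries = {}
    for name, model in result["models"].items():
        if model is None:
            summaries[name] = None
            continue
        summaries[name] = {
            "formula": model.formula,
            "adj_r2": model.adj_r2,
            "terms": model.terms.to_dict(orient="records"),
            "dropped": model.dropped,
        }
    write_json(out / "models.json", {**stamp, **summaries})
    report = "\n\n".join(stats.report(m) for m in result["models"].values()
                         if m is not None)
    (out / "report.txt").write_text(report + "\n")
    write_json(out / "run_log.json", {**stamp, "stages": result["logs"]})
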