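"""Clean the recordings, measure pinprick SEPs, and compare groups.

For every participant: 1-35 Hz zero-phase FIR, bad-channel screen, common-
average reference, segment rejection; then -0.5..1.5 s epochs, per-hand
averages, and the negative-positive peak measurement at the analysis
channel (ipsilesional for stroke, contralateral to the dominant hand for
controls). Caches the per-participant dB time-frequency maps for the later
steps and runs the one-way ANOVA of amplitude on group with Tukey
post-hocs and Cohen's d.
"""

import warnings

from common import RESULTS, SEED, compute_cohort_features, save_cache

from pinprick_tfr import stats

warnings.filterwarnings("ignore")

print(f"running cohort seed {SEED} through preprocessing + SEP + TFR ...")
data = compute_cohort_features()
save_cache(data)

sep = data["sep_table"]
out = RESULTS / "02_sep"
out.mkdir(parents=True, exist_ok=True)
sep.to_csv(out / "sep_measurements.csv", index=False)

print("\nmeasured SEP amplitude (uV) by group:")
print(sep.groupby("group")["np_amplitude"].agg(["mean", "std"]).round(2).to_string())

res = stats.anova_amplitude(sep)
(out / "anova.txt").write_text(stats.report(res) + "\n")
print("\n" + stats.report(res))
print(f"\ntables -> {out}")
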