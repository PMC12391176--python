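"""Extract per-participant ROI power and model it across groups.

Mean dB is taken over each discovered ROI's bins per participant, reshaped
to long form, and modeled as POWER ~ GROUP x FEATURE with a participant
random intercept, backward-reduced, with Tukey-corrected group contrasts
per feature. Writes the feature table used by the clinical step.
"""

import warnings

from common import RESULTS, SEED, load_cache

import pandas as pd
from pinprick_tfr import masking, stats
from pinprick_tfr.core import ROI_TO_FEATURE

warnings.filterwarnings("ignore")

data = load_cache()
disc = masking.discover_rois(data["tfrs"], masking.MaskConfig(), seed=SEED)

rows = []
for tfr in data["tfrs"]:
    rows.append({"participant": tfr.labels["participant"],
                 **masking.extract_roi_power(tfr, disc["rois"])})
roi_power = pd.DataFrame(rows).rename(
    columns={k: v for k, v in ROI_TO_FEATURE.items()})

features = (data["sep_table"][["participant", "group", "np_amplitude"]]
            .merge(roi_power, on="participant")
            .merge(data["clinical"].drop(columns=["group"]), on="participant"))
out = RESULTS / "04_features"
out.mkdir(parents=True, exist_ok=True)
features.to_csv(out / "features.csv", index=False)

value_cols = [c for c in ("delta", "theta", "alpha", "beta1", "beta2")
              if c in features]
print("mean ROI power (dB) by group:")
print(features.groupby("group")[value_cols].mean().round(2).to_string())

long = features.melt(id_vars=["participant", "group"], value_vars=value_cols,
                     var_name="feature", value_name="power")
res = stats.mixed_model_power(long)
(out / "mixed_model.txt").write_text(stats.report(res) + "\n")
print("\n" + stats.report(res))
print(f"\nfeature table -> {out / 'features.csv'}")
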