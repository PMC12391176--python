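"""Relate the EEG features to clinical scores in the stroke subset.

Backward-stepwise linear models of FMA, EmNSA and PTT — at the first
session and as session-2 minus session-1 change — on SEP amplitude, the
five ROI powers, stroke type, and every feature x type interaction
(n = 16 stroke participants, so treat retained terms as exploratory).
"""

import json
import warnings

from common import RESULTS, load_cache

import pandas as pd
from pinprick_tfr import stats

warnings.filterwarnings("ignore")

features = pd.read_csv(RESULTS / "04_features" / "features.csv") \
    if (RESULTS / "04_features" / "features.csv").exists() else None
if features is None:
    raise SystemExit("run analysis/04_roi_power_statistics.py first")
features = features.rename(columns={"np_amplitude": "amplitude"})

out = RESULTS / "05_clinical"
out.mkdir(parents=True, exist_ok=True)
summary = {}
for outcome in ("fma", "emnsa", "ptt"):
    for change in (False, True):
        key = f"{outcome}_{'change' if change else 't1'}"
        try:
            res = stats.clinical_regression(features, outcome, change)
        except Exception as exc:
            print(f"{key}: skipped ({exc})")
            summary[key] = {"error": str(exc)}
            continue
        summary[key] = {"formula": res.formula, "adj_r2": res.adj_r2,
                        "terms": res.terms.to_dict(orient="records")}
        print(f"\n{stats.report(res)}")

(out / "models.json").write_text(json.dumps(summary, indent=1))
print(f"\nmodel summaries -> {out / 'models.json'}")
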