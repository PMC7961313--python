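"""Score the pipeline against ground truth: confusion metrics and the funnel.

Applies the part-level scoring definitions (a truly major part fully and
correctly identified is a TP; a missed major part an FN; a stray or wrong
major identification an FP) and prints the attrition funnel with Wilson 95%
intervals plus the per-reason error tallies.
"""

import json
import sys

import pandas as pd
import yaml

sys.path.insert(0, ".")
from analysis.common import path  # noqa: E402

from implantreg import metrics  # noqa: E402
from implantreg.config import CatalogOverrides, PipelineConfig  # noqa: E402

mapping = pd.read_csv(path("mapping.csv"), keep_default_na=False)
gt_parts = pd.read_csv(path("ground_truth_parts.csv"))
overrides = CatalogOverrides.model_validate(yaml.safe_load(open(path("overrides.yaml"))))
pcfg = PipelineConfig(overrides=overrides)

conf, funnel = metrics.evaluate_pipeline(mapping, gt_parts, pcfg)
m = metrics.confusion_metrics(conf)

funnel.to_frame().to_csv(path("funnel.csv"), index=False)
with open(path("metrics.json"), "w") as fh:
    json.dump({"confusion": conf.__dict__, "metrics": m,
               "error_tallies": funnel.error_tallies}, fh, indent=2)

print(f"parts scored: {conf.total} "
      f"(tp {conf.tp}, tn {conf.tn}, fp {conf.fp}, fn {conf.fn})")
print("  " + ", ".join(f"{k} {100 * v:.0f}%" for k, v in m.items()))
print("funnel (major parts needing identification):")
for row in funnel.to_frame().itertuples(index=False):
    ci = ("" if pd.isna(row.percent)
          else f" {row.percent:.0f}% [{row.ci_lower:.0f}-{row.ci_upper:.0f}]")
    print(f"  {row.stage:24s} {row.count:6d}{ci}")
print("error tallies: "
      + ", ".join(f"{k}: {v}" for k, v in sorted(funnel.error_tallies.items(),
                                                 key=lambda kv: -kv[1])))
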