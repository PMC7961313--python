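"""Generate the demonstration EHR cohort.

Writes the synthetic health-system tables (surgeries, encounters, deaths),
the GUDID-like device catalog, the curated override maps, and the ground
truth the later validation step scores against. Prints the cohort's shape:
procedure counts, demographics and the injected error burden.
"""

import sys

import yaml

sys.path.insert(0, ".")
from analysis.common import demo_config, path  # noqa: E402

from implantreg import synthetic  # noqa: E402

cfg = demo_config()
cat = synthetic.generate_catalog(cfg.simulation)
cohort = synthetic.generate_cohort(cfg.simulation, cat)
paths = synthetic.write_cohort(cohort, cat, path(""))
with open(path("overrides.yaml"), "w") as fh:
    yaml.safe_dump(cat.overrides.model_dump(), fh)
with open(path("config.yaml"), "w") as fh:
    yaml.safe_dump(cfg.model_dump(mode="json"), fh)

gt = cohort.gt_surgeries
patients = gt.drop_duplicates("patient_id")
n_rev = (gt.true_type == "revision").sum()
print(f"cohort: {len(gt)} surgeries on {gt.patient_id.nunique()} patients "
      f"({cfg.simulation.year_range[0]}-{cfg.simulation.year_range[1]})")
print(f"  male {100 * patients.patient_male.mean():.1f}%, "
      f"mean age {patients.patient_age.mean():.1f}")
print(f"  {n_rev} revision and {(gt.true_type == 'removal').sum()} "
      f"removal surgeries recorded in-system")
corrupt = cohort.gt_parts[[c for c in cohort.gt_parts if c.startswith("corrupt_")]]
print(f"  {len(cohort.gt_parts)} part entries; injected error rates: "
      + ", ".join(f"{k.removeprefix('corrupt_')} {100 * v:.1f}%"
                  for k, v in corrupt.mean().items()))
print(f"  catalog: {len(cat.catalog)} sized entries; "
      f"{len(cat.legacy)} legacy entries deliberately absent")
print("wrote:", ", ".join(sorted(paths)))
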