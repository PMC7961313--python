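"""Type procedures, parse sides, clean part numbers and map them to the catalog.

Reads surgeries.csv and catalog.csv from the simulation step, applies the
extraction rules and the catalog lookup (with the curated class overrides),
and reports how much of the free-text record survived each hurdle.
"""

import sys

import pandas as pd
import yaml

sys.path.insert(0, ".")
from analysis.common import path  # noqa: E402

from implantreg import catalog as cm  # noqa: E402
from implantreg import extraction  # noqa: E402
from implantreg.config import CatalogOverrides, PipelineConfig  # noqa: E402

surgeries = pd.read_csv(path("surgeries.csv"), keep_default_na=False)
overrides = CatalogOverrides.model_validate(yaml.safe_load(open(path("overrides.yaml"))))
pcfg = PipelineConfig(overrides=overrides)

typed = extraction.extract_procedures(surgeries, pcfg)
catalog = cm.Catalog.from_csv(path("catalog.csv"), overrides)
mapping = cm.map_parts(typed, catalog, pcfg)

extraction.typed_to_csv(typed, path("typed_procedures.csv"))
mapping.to_csv(path("mapping.csv"), index=False)

print(f"typed {len(typed)} surgeries: "
      + ", ".join(f"{k} {v}" for k, v in
                  typed.procedure_type.value_counts().items()))
print(f"side parsed: {(typed.side != 'unknown').mean() * 100:.1f}% known")
n = len(mapping)
print(f"{n} part entries cleaned; mapping outcomes: "
      + ", ".join(f"{k} {v}" for k, v in mapping.status.value_counts().items()))
ci = (mapping.match_mode == "case_insensitive").sum()
print(f"  {ci} entries rescued by the case-insensitive fallback")
major = mapping[mapping.is_major]
print(f"  {len(major)} major components identified "
      f"({major.component_class.value_counts().to_dict()})")
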