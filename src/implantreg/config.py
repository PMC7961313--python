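"""Configuration models for the synthetic EHR generator and the extraction pipeline.

Two configuration trees exist:

* :class:`SimulationConfig` — everything the synthetic-data generator needs:
  cohort size and demographics, per-year procedure volumes, the data-entry
  error taxonomy (probabilities per error mode), per-model failure hazards,
  and censoring processes (death, encounter cadence, out-of-system revision).
* :class:`PipelineConfig` — everything the extraction/mapping/linkage/survival
  pipeline needs: the CPT code map, side-parsing token lists, part-number
  cleaning tokens, catalog override maps, and survivorship thresholds.

Both are pydantic models so invalid configs fail loudly, naming the field.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

STUDY_START_YEAR = 2000
STUDY_END_YEAR = 2017

#: Per-year primary THA volumes in the emulated health system, 2000-2017.
#: A roughly linear ramp from ~360 to ~3750 procedures/year; used as relative
#: weights when the cohort is scaled down.
DEFAULT_ANNUAL_VOLUME = [
    359, 420, 560, 700, 850, 1000, 1200, 1400, 1650, 1900,
    2150, 2400, 2650, 2900, 3150, 3400, 3600, 3750,
]


class ErrorRates(BaseModel):
    """Per-part probabilities of each data-entry error mode.

    Defaults are the observed frequencies of each error reason among the 391
    major parts of a 100-case manual audit of the source EHR (missing field
    39/391, number in wrong record 14/391, excess characters 11/391, wrong
    number 5/391, legacy/old part 14/391, case mismatch 3/391).
    """

    model_config = ConfigDict(extra="forbid")

    missing_part: float = 39 / 391
    wrong_record: float = 14 / 391
    excess_chars: float = 11 / 391
    wrong_digits: float = 5 / 391
    legacy_part: float = 14 / 391
    case_flip: float = 3 / 391

    @field_validator("*")
    @classmethod
    def _prob(cls, v: float, info) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must be a probability in [0, 1], got {v}")
        return v

    @classmethod
    def zero(cls) -> "ErrorRates":
        return cls(missing_part=0, wrong_record=0, excess_chars=0,
                   wrong_digits=0, legacy_part=0, case_flip=0)


class WeibullHazard(BaseModel):
    """Weibull failure-time parameters for one implant model.

    ``scale_rel`` is a *relative* scale multiplier applied to the globally
    calibrated base scale (years): ``scale_rel = 0.25`` means the model's
    characteristic life is a quarter of the cohort baseline, i.e. a 4x hazard
    scale disadvantage. ``shape`` falls back to the global shape when None.
    """

    model_config = ConfigDict(extra="forbid")

    shape: Optional[float] = None
    scale_rel: float = 1.0

    @field_validator("shape")
    @classmethod
    def _shape(cls, v):
        if v is not None and v <= 0:
            raise ValueError(f"shape must be positive, got {v}")
        return v

    @field_validator("scale_rel")
    @classmethod
    def _scale(cls, v):
        if v <= 0:
            raise ValueError(f"scale_rel must be positive, got {v}")
        return v


class CeramicAdoption(BaseModel):
    """Logistic adoption curve for ceramic (vs metal) femoral heads.

    P(ceramic | year) = 1 / (1 + exp(-(year - midpoint) / slope)).

    Defaults place the 50% crossing mid-2015/2016 with ~45%/54% ceramic in
    2015/2016, matching the national trend the emulated registry tracked.
    """

    model_config = ConfigDict(extra="forbid")

    midpoint: float = 2015.5
    slope: float = 2.49

    def ceramic_prob(self, year):
        import numpy as np

        return 1.0 / (1.0 + np.exp(-(np.asarray(year, dtype=float) - self.midpoint) / self.slope))


class SimulationConfig(BaseModel):
    """Full specification of one synthetic EHR cohort."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = 5000
    year_range: tuple[int, int] = (STUDY_START_YEAR, STUDY_END_YEAR)
    annual_volume_curve: Optional[list[float]] = None
    revision_fraction: float = 0.047
    male_fraction: float = 0.947
    age_mean_sd: tuple[float, float] = (63.7, 10.1)
    error_rates: ErrorRates = Field(default_factory=ErrorRates)
    #: per-year overrides of the error taxonomy; unlisted years use `error_rates`
    error_rates_by_year: dict[int, ErrorRates] = Field(default_factory=dict)
    #: per-model hazard overrides keyed by model key (6-char prefix)
    model_hazards: dict[str, WeibullHazard] = Field(default_factory=dict)
    weibull_shape: float = 1.5
    out_of_system_revision_rate: float = 0.15
    mortality_rate: float = 0.03  # per-year exponential hazard from surgery
    encounter_gap_mean: float = 180.0  # days
    mate_replacement_prob: float = 0.5
    removal_fraction: float = 0.02  # failures treated by removal without replacement
    minor_parts_prob: float = 0.4
    ceramic_adoption: CeramicAdoption = Field(default_factory=CeramicAdoption)
    # catalog shape
    n_models: dict[str, int] = Field(
        default_factory=lambda: {"shell": 10, "liner": 8, "stem": 10,
                                 "head_metal": 6, "head_ceramic": 6, "minor": 4}
    )
    sizes_per_model: int = 5
    legacy_fraction: float = 0.1  # fraction of models per class absent from the catalog
    monoblock_shell_models: int = 1
    miscategorized_stem_models: int = 1  # stems whose catalog term says femoral head
    #: 0 = uniform model usage within a class; larger = more head-heavy (Zipf-like)
    model_usage_concentration: float = 1.0
    seed: int = 0

    @field_validator("n_patients", "sizes_per_model", "monoblock_shell_models",
                     "miscategorized_stem_models")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("revision_fraction", "male_fraction", "out_of_system_revision_rate",
                     "mate_replacement_prob", "removal_fraction", "minor_parts_prob",
                     "legacy_fraction")
    @classmethod
    def _prob(cls, v, info):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must be in [0, 1], got {v}")
        return v

    @field_validator("mortality_rate", "encounter_gap_mean", "weibull_shape")
    @classmethod
    def _pos(cls, v, info):
        if v <= 0 and info.field_name != "mortality_rate":
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _years(self):
        start, end = self.year_range
        if start > end:
            raise ValueError(f"year_range start {start} exceeds end {end}")
        if self.annual_volume_curve is not None:
            n_years = end - start + 1
            if len(self.annual_volume_curve) != n_years:
                raise ValueError(
                    f"annual_volume_curve has {len(self.annual_volume_curve)} entries "
                    f"for a {n_years}-year range"
                )
            if any(v < 0 for v in self.annual_volume_curve):
                raise ValueError("annual_volume_curve entries must be >= 0")
        return self

    @property
    def years(self) -> list[int]:
        return list(range(self.year_range[0], self.year_range[1] + 1))

    def volume_weights(self):
        import numpy as np

        if self.annual_volume_curve is not None:
            w = np.asarray(self.annual_volume_curve, dtype=float)
        else:
            n = len(self.years)
            base = np.asarray(DEFAULT_ANNUAL_VOLUME, dtype=float)
            if n == len(base):
                w = base
            else:  # non-default year range: linear ramp with the same endpoints
                w = np.linspace(base[0], base[-1], n)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("annual_volume_curve sums to zero")
        return w / tot


# ---------------------------------------------------------------------------
# Pipeline configuration


DEFAULT_CODE_MAP = {
    "27130": "primary",
    "27132": "primary",
    "27134": "revision",
    "27137": "revision",
    "27138": "revision",
    "27090": "removal",
    "27091": "removal",
}

DEFAULT_LEFT_TOKENS = [r"\bLEFT\b", r"\bLT\b", r"\bL\b(?=\s+(?:TOTAL|HIP|THA))"]
DEFAULT_RIGHT_TOKENS = [r"\bRIGHT\b", r"\bRT\b", r"\bR\b(?=\s+(?:TOTAL|HIP|THA))"]
DEFAULT_BILATERAL_TOKENS = [r"\bBILATERAL\b", r"\bBILAT\b", r"\bB/L\b"]

#: standalone tokens stripped from the ends of a raw part-number string
DEFAULT_STRIP_TOKENS = ["REF", "LOT", "REF#", "#", "*"]


class CatalogOverrides(BaseModel):
    """Hand-curated corrections layered over the device catalog.

    ``enrichment`` adds catalog rows for legacy parts absent from the base
    catalog; ``class_overrides`` forces a component class for a model prefix
    whose catalog category term is wrong; ``aggregation_overrides`` maps part
    numbers (exact or prefix) to a model key where the first-6-characters
    rule fails.
    """

    model_config = ConfigDict(extra="forbid")

    enrichment: list[dict] = Field(default_factory=list)
    class_overrides: dict[str, str] = Field(default_factory=dict)
    aggregation_overrides: dict[str, str] = Field(default_factory=dict)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    code_map: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_CODE_MAP))
    left_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_LEFT_TOKENS))
    right_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_RIGHT_TOKENS))
    bilateral_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_BILATERAL_TOKENS))
    strip_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_STRIP_TOKENS))
    case_insensitive_fallback: bool = True
    model_prefix_length: int = 6
    min_uses: int = 100  # models below this are not given survivorship curves
    min_at_risk: int = 10  # CI comparison truncated where either arm drops below
    ci_method: str = "exp_greenwood"  # or "greenwood"
    overrides: CatalogOverrides = Field(default_factory=CatalogOverrides)

    @field_validator("ci_method")
    @classmethod
    def _ci(cls, v):
        if v not in ("exp_greenwood", "greenwood"):
            raise ValueError(f"ci_method must be 'exp_greenwood' or 'greenwood', got {v!r}")
        return v

    @field_validator("code_map")
    @classmethod
    def _codes(cls, v):
        allowed = {"primary", "revision", "removal", "other"}
        for code, typ in v.items():
            if typ not in allowed:
                raise ValueError(f"code_map[{code!r}] = {typ!r} not in {sorted(allowed)}")
        return v


class RunConfig(BaseModel):
    """Top-level config: one simulation + one pipeline + output location."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    pipeline: PipelineConfig = Field(default_factory=PipelineConfig)
    output_dir: str = "results/run"


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys raise a validation error naming them."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
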