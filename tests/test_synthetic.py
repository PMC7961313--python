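"""Generator contracts: construction rules, determinism, error injection, truth."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from implantreg.config import ErrorRates, SimulationConfig, WeibullHazard
from implantreg.synthetic import generate_catalog, generate_cohort


def small_config(**kw):
    base = dict(n_patients=300, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_probability_bounds_name_field(self):
        with pytest.raises(ValidationError, match="missing_part"):
            ErrorRates(missing_part=1.5)

    def test_year_range_order(self):
        with pytest.raises(ValidationError, match="year_range"):
            SimulationConfig(year_range=(2018, 2005))

    def test_volume_curve_length(self):
        with pytest.raises(ValidationError, match="annual_volume_curve"):
            SimulationConfig(year_range=(2010, 2012), annual_volume_curve=[1.0])

    def test_negative_count(self):
        with pytest.raises(ValidationError, match="n_patients"):
            SimulationConfig(n_patients=-1)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError, match="mystery"):
            SimulationConfig(mystery=3)


class TestCatalogConstruction:
    def test_models_times_sizes(self):
        cfg = small_config(
            n_models={"shell": 10, "liner": 0, "stem": 0, "head_metal": 0,
                      "head_ceramic": 0, "minor": 0},
            sizes_per_model=5, legacy_fraction=0.0,
            monoblock_shell_models=0, miscategorized_stem_models=0)
        cat = generate_catalog(cfg)
        assert len(cat.catalog) == 50
        assert cat.catalog.part_number.str.slice(0, 6).nunique() == 10

    def test_legacy_fraction_zero_all_resolvable(self):
        cfg = small_config(legacy_fraction=0.0)
        cat = generate_catalog(cfg)
        cohort = generate_cohort(cfg, cat)
        assert cohort.gt_parts.part_number.isin(set(cat.catalog.part_number)).all()

    def test_legacy_parts_absent_from_catalog(self):
        cat = generate_catalog(small_config())
        assert not cat.legacy.part_number.isin(set(cat.catalog.part_number)).any()
        # ground-truth part numbers all resolve in the uncorrupted full universe
        assert set(cat.legacy.part_number) <= cat.all_part_numbers

    def test_determinism(self):
        a = generate_catalog(small_config())
        b = generate_catalog(small_config())
        pd.testing.assert_frame_equal(a.catalog, b.catalog)

    def test_miscategorized_stem_has_corrective_override(self):
        cat = generate_catalog(small_config())
        assert cat.overrides.class_overrides  # at least the default one stem
        for mk, cls in cat.overrides.class_overrides.items():
            assert cls == "stem"
            rows = cat.catalog[cat.catalog.part_number.str.startswith(mk)]
            assert (rows.category_term.str.contains("HEAD")).all()


class TestCohortGeneration:
    def test_determinism_byte_identical(self):
        cfg = small_config()
        cat = generate_catalog(cfg)
        a = generate_cohort(cfg, cat)
        b = generate_cohort(cfg, cat)
        for name in ("surgeries", "encounters", "deaths", "gt_surgeries",
                     "gt_components", "gt_parts"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_component_conservation(self):
        cfg = small_config()
        cohort = generate_cohort(cfg, generate_catalog(cfg))
        gt = cohort.gt_components
        assert gt.component_id.is_unique
        assert (gt.true_end_reason != "").all()
        assert (pd.to_datetime(gt.true_end_date)
                >= pd.to_datetime(gt.implant_date)).all()

    def test_revisions_never_predate_primary(self):
        cfg = small_config(n_patients=1500, seed=2)
        cohort = generate_cohort(cfg, generate_catalog(cfg))
        gt = cohort.gt_surgeries
        prim = gt[gt.true_type == "primary"].set_index("patient_id").surgery_date
        rev = gt[gt.true_type != "primary"]
        assert (pd.to_datetime(rev.surgery_date).to_numpy()
                >= pd.to_datetime(rev.patient_id.map(prim)).to_numpy()).all()

    def test_death_after_last_encounter(self):
        cfg = small_config(n_patients=800, seed=3)
        cohort = generate_cohort(cfg, generate_catalog(cfg))
        last = (cohort.encounters.assign(d=pd.to_datetime(cohort.encounters.encounter_date))
                .groupby("patient_id").d.max())
        dd = cohort.deaths.set_index("patient_id").death_date
        both = last.index.intersection(dd.index)
        assert (pd.to_datetime(dd.loc[both]) >= last.loc[both]).all()

    def test_missing_rate_binomial(self):
        """Injected missing-entry fraction stays within 3 binomial SDs of the
        configured rate."""
        p = 0.10
        cfg = small_config(n_patients=600, seed=17,
                           error_rates=ErrorRates(missing_part=p, wrong_record=0,
                                                  excess_chars=0, wrong_digits=0,
                                                  legacy_part=0, case_flip=0))
        cohort = generate_cohort(cfg, generate_catalog(cfg))
        n = len(cohort.gt_parts)
        assert n > 2000
        frac = cohort.gt_parts.corrupt_missing.mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_outlier_hazard_fails_more(self):
        """A model with half the Weibull scale of its peers shows a higher
        empirical failure proportion at 5 years in the generated truth."""
        cfg = small_config(
            n_patients=6000, seed=23, error_rates=ErrorRates.zero(),
            out_of_system_revision_rate=0.0, legacy_fraction=0.0,
            revision_fraction=0.15,  # enough failure events for a stable MC check
            monoblock_shell_models=0, model_usage_concentration=0.0,
            model_hazards={"SH0001": WeibullHazard(scale_rel=0.5)})
        cohort = generate_cohort(cfg, generate_catalog(cfg))
        gt = cohort.gt_components
        shells = gt[(gt.component_class == "shell")]
        dur = (pd.to_datetime(shells.true_end_date)
               - pd.to_datetime(shells.implant_date)).dt.days
        failed5 = (shells.true_end_reason.str.startswith("failed")
                   & (dur <= 5 * 365.25))
        by_model = failed5.groupby(shells.model_key).mean()
        outlier = by_model.pop("SH0001")
        assert outlier > by_model.max()

    def test_wrong_digits_absent_from_catalog(self):
        cfg = small_config(n_patients=1000, seed=29,
                           error_rates=ErrorRates(missing_part=0, wrong_record=0,
                                                  excess_chars=0, wrong_digits=0.3,
                                                  legacy_part=0, case_flip=0))
        cat = generate_catalog(cfg)
        cohort = generate_cohort(cfg, cat)
        bad = cohort.gt_parts[cohort.gt_parts.corrupt_wrong_digits]
        assert len(bad) > 100
        assert not bad.entry_text.isin(cat.all_part_numbers).any()

    def test_out_of_system_truncates_encounters(self):
        cfg = small_config(n_patients=2000, seed=31,
                           out_of_system_revision_rate=1.0)
        cohort = generate_cohort(cfg, generate_catalog(cfg))
        oos = cohort.gt_components[
            cohort.gt_components.true_end_reason == "failed_out_of_system"]
        assert len(oos) > 0
        last = (cohort.encounters.assign(d=pd.to_datetime(cohort.encounters.encounter_date))
                .groupby("patient_id").d.max())
        first_oos = (oos.assign(d=pd.to_datetime(oos.true_end_date))
                     .groupby("patient_id").d.min())
        assert (last.loc[first_oos.index] < first_oos).all()
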