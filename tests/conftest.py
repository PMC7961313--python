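"""Shared fixtures: small synthetic cohorts run through the pipeline once."""

from __future__ import annotations

import numpy as np
import pytest

from implantreg import catalog as cm
from implantreg import extraction, linkage, synthetic
from implantreg.config import ErrorRates, PipelineConfig, SimulationConfig

STUDY_END = np.datetime64("2017-12-31")


def run_pipeline(sim: SimulationConfig, pcfg: PipelineConfig | None = None):
    """Generate a cohort and run extract -> map -> link; returns a dict of stages."""
    cat = synthetic.generate_catalog(sim)
    cohort = synthetic.generate_cohort(sim, cat)
    cfg = (pcfg or PipelineConfig()).model_copy(deep=True)
    cfg.overrides.class_overrides = {
        **cat.overrides.class_overrides, **cfg.overrides.class_overrides}
    typed = extraction.extract_procedures(cohort.surgeries, cfg)
    mapping = cm.map_parts(typed, cm.Catalog(cat.catalog, cfg.overrides), cfg)
    episodes, report = linkage.link_episodes(
        typed, mapping, cohort.encounters, cohort.deaths, STUDY_END)
    return {"sim": sim, "pcfg": cfg, "catalog": cat, "cohort": cohort,
            "typed": typed, "mapping": mapping, "episodes": episodes,
            "link_report": report}


@pytest.fixture(scope="session")
def clean_run():
    """Zero-error, fully observed cohort: the pipeline should be lossless."""
    sim = SimulationConfig(n_patients=400, seed=5, error_rates=ErrorRates.zero(),
                           out_of_system_revision_rate=0.0)
    return run_pipeline(sim)


@pytest.fixture(scope="session")
def noisy_run():
    """Default (audit-calibrated) error rates; realistic loss pattern."""
    sim = SimulationConfig(n_patients=800, seed=9)
    return run_pipeline(sim)


@pytest.fixture(scope="session")
def default_catalog():
    return synthetic.generate_catalog(SimulationConfig(n_patients=10, seed=0))
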