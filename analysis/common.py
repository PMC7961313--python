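"""Shared settings for the numbered analysis scripts.

One deterministic demonstration cohort (5000 patients, seed 42) flows through
the whole pipeline; every script reads its inputs from RESULTS and writes its
outputs back there, so the scripts can be run in order or re-run singly.
"""

from __future__ import annotations

import os

from implantreg.config import RunConfig, SimulationConfig

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")

STUDY_END = "2017-12-31"


def demo_config() -> RunConfig:
    return RunConfig(
        simulation=SimulationConfig(n_patients=5000, seed=42),
        output_dir=RESULTS,
    )


def path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
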