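"""Pipeline accuracy assessment: confusion metrics, Wilson intervals, funnel.

Scoring definitions (over all parts, major and minor):

* true positive — a truly major part fully and correctly identified as a
  major part of the right class;
* true negative — a truly minor part not identified as a major part;
* false positive — an identification as a major part that is wrong (a stray
  or misclassified identification);
* false negative — a truly major part not identified as a major part.

The attrition funnel tracks, for the major parts needing identification, how
many survive each stage — part number present in the record, number entered
correctly, number present in the catalog, mapped, and fully classified —
with each lost part tallied by its first failing stage's reason. Stage
percentages carry Wilson score 95% intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PipelineConfig

FUNNEL_STAGES = ["needing_identification", "found_in_record", "number_correct",
                 "in_catalog", "mapped", "classified"]

REASONS = {
    "missing": "Missing data",
    "wrong_record": "Part No. entered into wrong record",
    "excess_chars": "Excess characters not interpreted correctly",
    "wrong_digits": "Wrong No. entered",
    "legacy": "Old part No.",
    "case": "Upper vs lower case letter",
    "too_short": "Part No. too short",
    "unmapped_other": "Not mapped, other",
    "misclassified": "Component class misidentified",
}


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FunnelReport:
    counts: dict = field(default_factory=dict)       # stage -> count
    percents: dict = field(default_factory=dict)     # stage -> (% , lo%, hi%)
    error_tallies: dict = field(default_factory=dict)  # reason -> count

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in FUNNEL_STAGES:
            if stage not in self.counts:
                continue
            pct = self.percents.get(stage)
            rows.append({
                "stage": stage, "count": self.counts[stage],
                "percent": None if pct is None else pct[0],
                "ci_lower": None if pct is None else pct[1],
                "ci_upper": None if pct is None else pct[2],
            })
        return pd.DataFrame(rows)


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 as proportions.

    A metric whose denominator is zero is reported as None, not 0.
    """
    if c.total <= 0:
        raise ValueError("confusion metrics need at least one classified part")
    out: dict[str, Optional[float]] = {}
    out["accuracy"] = (c.tp + c.tn) / c.total
    out["precision"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    out["recall"] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    p, r = out["precision"], out["recall"]
    if p is None or r is None or (p + r) == 0:
        out["f1"] = None
    else:
        out["f1"] = 2 * p * r / (p + r)
    return out


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    Centre (p + z^2/2n) / (1 + z^2/n), half-width
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n).
    """
    if n < 1:
        raise ValueError("wilson_interval requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"successes k={k} outside [0, n={n}]")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    z = norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def _first_failure_reason(row) -> str:
    """Attribute one lost major part to its first failing funnel stage."""
    if row.corrupt_missing:
        return REASONS["missing"]
    if row.corrupt_wrong_record:
        return REASONS["wrong_record"]
    if row.corrupt_wrong_digits:
        return REASONS["wrong_digits"]
    if not row.found_clean:  # cleaning failed to recover the number
        return REASONS["excess_chars"]
    if row.is_legacy:
        return REASONS["legacy"]
    if row.status != "mapped":
        if row.corrupt_case_flip:
            return REASONS["case"]
        if len(str(row.cleaned)) < 6:
            return REASONS["too_short"]
        return REASONS["unmapped_other"]
    return REASONS["misclassified"]


def evaluate_pipeline(mapping: pd.DataFrame, gt_parts: pd.DataFrame,
                      config: PipelineConfig | None = None
                      ) -> tuple[ConfusionCounts, FunnelReport]:
    """Score the pipeline's per-part output against ground truth.

    ``gt_parts`` is the generator's part-level truth (or a manual-review file
    in the same schema). Every evaluated surgery must be covered by truth;
    pipeline rows for surgeries absent from truth raise a validation error.

    A part counts as *fully identified* only if its number was extracted from
    its own surgical record, mapped in the catalog, and classified with the
    correct component class — the full conjunction.
    """
    cfg = config or PipelineConfig()
    truth_sids = set(gt_parts.surgery_id) | set(gt_parts.entry_surgery_id)
    extra = sorted(set(mapping.surgery_id) - truth_sids)
    if extra:
        raise ValueError(f"pipeline output for surgeries absent from truth: {extra[:10]}")

    mp = mapping[["surgery_id", "entry_index", "cleaned", "status", "match_mode",
                  "component_class"]].rename(columns={"component_class": "pipeline_class"})
    gt = gt_parts.merge(
        mp, left_on=["entry_surgery_id", "entry_index"],
        right_on=["surgery_id", "entry_index"], how="left", suffixes=("", "_pl"))

    gt["in_own_record"] = gt.entry_surgery_id == gt.surgery_id
    gt["cleaned"] = gt.cleaned.fillna("")
    gt["status"] = gt.status.fillna("missing")
    gt["pipeline_class"] = gt.pipeline_class.fillna("")
    # cleaning recovered the entered number (case-insensitively; case repair
    # is the catalog layer's job and is audited at the mapping stage)
    entered_ok = ~(gt.corrupt_missing | gt.corrupt_wrong_digits)
    gt["found_clean"] = (gt.in_own_record
                         & (gt.cleaned.str.upper() == gt.part_number.str.upper()))
    gt["number_correct"] = gt.found_clean & entered_ok
    gt["fully_identified"] = (gt.in_own_record & (gt.status == "mapped")
                              & (gt.pipeline_class == gt.component_class))

    is_major = gt.component_class.isin(["shell", "liner", "stem", "head"])
    major = gt[is_major]
    minor = gt[~is_major]

    c = ConfusionCounts()
    c.tp = int(major.fully_identified.sum())
    c.fn = int((~major.fully_identified).sum())
    # a minor part identified as major is a false positive
    minor_wrong = (minor.in_own_record & (minor.status == "mapped")
                   & minor.pipeline_class.isin(["shell", "liner", "stem", "head"]))
    c.fp = int(minor_wrong.sum())
    c.tn = int(len(minor) - minor_wrong.sum())

    # stray identifications: a mapped major-class entry in a surgery where the
    # part was never implanted (numbers relocated into the wrong record) is a
    # wrong assertion of a major part — a false positive for that surgery
    majors = ["shell", "liner", "stem", "head"]
    mapped_major = mp[(mp.status == "mapped") & mp.pipeline_class.isin(majors)]
    link = mapped_major.merge(
        gt_parts[["surgery_id", "entry_surgery_id", "entry_index"]],
        left_on=["surgery_id", "entry_index"],
        right_on=["entry_surgery_id", "entry_index"],
        how="left", suffixes=("", "_gt"))
    stray_fp = int((link.surgery_id_gt.isna()
                    | (link.surgery_id_gt != link.surgery_id)).sum())
    c.fp += stray_fp

    # --- funnel over major parts needing identification ----------------------
    n0 = len(major)
    found = major.corrupt_missing == False  # noqa: E712  (entered somewhere)
    number_ok = major.number_correct
    in_cat = number_ok & ~major.is_legacy
    mapped_ok = major.in_own_record & (major.status == "mapped")
    classified = major.fully_identified

    rep = FunnelReport()
    rep.counts["needing_identification"] = n0
    stages = [("found_in_record", found), ("number_correct", number_ok),
              ("in_catalog", in_cat), ("mapped", mapped_ok & in_cat),
              ("classified", classified & in_cat & mapped_ok)]
    for name, mask in stages:
        k = int(mask.sum())
        rep.counts[name] = k
        if n0 > 0:
            lo, hi = wilson_interval(k, n0)
            rep.percents[name] = (100.0 * k / n0, 100.0 * lo, 100.0 * hi)

    lost = major[~major.fully_identified]
    tallies: dict[str, int] = {}
    for row in lost.itertuples(index=False):
        reason = _first_failure_reason(row)
        tallies[reason] = tallies.get(reason, 0) + 1
    rep.error_tallies = tallies
    return c, rep
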