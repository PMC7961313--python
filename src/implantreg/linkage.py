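"""Build per-patient, per-side surgery timelines and infer component removals.

The central inference: if a component class (say, a stem) is newly placed at
a revision, the in-situ component of that class must have been removed at
that revision. Removal-coded surgeries end every in-situ component.
Components never replaced are censored at the last health-system encounter,
at death, or at the study end.

A monoblock shell (one part number covering shell + articulating head)
occupies both the shell and head classes: placing either a new shell or a
new head removes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import MAJOR_CLASSES

log = logging.getLogger(__name__)


@dataclass
class ComponentEpisode:
    """One implanted major component's life, implantation to end of observation."""

    patient_id: str
    side: str
    component_class: str
    model_key: str
    part_number: str
    implant_date: np.datetime64
    end_date: np.datetime64
    end_reason: str                  # removed | censored_alive | censored_dead
    source_surgery_id: object
    removal_surgery_id: Optional[object] = None

    @property
    def duration_days(self) -> int:
        return int((self.end_date - self.implant_date).astype("timedelta64[D]").astype(int))


@dataclass
class LinkageReport:
    """Per-run accounting of records excluded or flagged during linkage."""

    unknown_side_surgeries: int = 0
    orphan_revisions: int = 0
    duplicate_class_parts: int = 0
    merged_same_day: int = 0
    details: list = field(default_factory=list)


def build_timelines(typed: pd.DataFrame, mapping: pd.DataFrame,
                    report: LinkageReport | None = None) -> dict:
    """Group typed procedures into date-ordered (patient, side) timelines.

    Surgeries with unknown side are excluded (and counted in the report);
    same-day surgeries on one side merge into a single surgical event whose
    placed-part list is the union. Each event carries the mapped major parts
    placed at that surgery.
    """
    rep = report if report is not None else LinkageReport()
    major = mapping[mapping.is_major] if len(mapping) else mapping
    parts_by_surgery: dict = {}
    if len(major):
        for sid, grp in major.groupby("surgery_id"):
            parts_by_surgery[sid] = [
                {"component_class": g.component_class, "model_key": g.model_key,
                 "part_number": g.part_number, "is_monoblock": bool(g.is_monoblock)}
                for g in grp.itertuples(index=False)]

    timelines: dict = {}
    usable = typed[typed.procedure_type.isin(["primary", "revision", "removal"])]
    n_unknown = int((usable.side == "unknown").sum())
    rep.unknown_side_surgeries += n_unknown
    if n_unknown:
        log.info("excluding %d unknown-side surgeries from linkage", n_unknown)
    usable = usable[usable.side != "unknown"]

    for r in usable.itertuples(index=False):
        key = (r.patient_id, r.side)
        timelines.setdefault(key, []).append({
            "surgery_id": r.surgery_id,
            "date": np.datetime64(str(r.surgery_date)[:10], "D"),
            "procedure_type": r.procedure_type,
            "parts": parts_by_surgery.get(r.surgery_id, []),
        })

    merged = {}
    for key, events in timelines.items():
        events.sort(key=lambda e: (e["date"], e["surgery_id"]))
        out = []
        for ev in events:
            if out and out[-1]["date"] == ev["date"]:
                prev = out[-1]
                prev["parts"] = prev["parts"] + ev["parts"]
                # a removal or revision code on the day dominates a primary code
                order = {"removal": 0, "revision": 1, "primary": 2}
                if order[ev["procedure_type"]] < order[prev["procedure_type"]]:
                    prev["procedure_type"] = ev["procedure_type"]
                rep.merged_same_day += 1
            else:
                out.append(dict(ev))
        merged[key] = out
    return merged


def _classes_of(part: dict) -> frozenset:
    if part["is_monoblock"]:
        return frozenset({"shell", "head"})
    return frozenset({part["component_class"]})


def infer_removals(timeline: list, last_encounter: Optional[np.datetime64],
                   death_date: Optional[np.datetime64], study_end: np.datetime64,
                   patient_id: str, side: str,
                   report: LinkageReport | None = None) -> list[ComponentEpisode]:
    """Walk one (patient, side) timeline and emit component episodes.

    At each revision, every component class with a newly placed part closes
    the in-situ component of that class (reason ``removed``) and opens a new
    episode. Removal-coded surgeries close everything in situ. Components
    still in situ at the end are censored at death if death occurred during
    the study, else at the last encounter (bounded by the study end).

    A revision with nothing in situ opens episodes anyway and is flagged as an
    orphan (primaries done outside the system exist in real data). When one
    surgery places two parts of the same class, the first by record order
    wins and the duplicate is logged.
    """
    rep = report if report is not None else LinkageReport()
    in_situ: dict[str, dict] = {}  # class -> {"episode_open": dict, "classes": frozenset}
    episodes: list[ComponentEpisode] = []

    def close(classes_to_close: set, date, reason: str, rsid):
        seen = set()
        for cls in list(classes_to_close):
            st = in_situ.get(cls)
            if st is None or id(st) in seen:
                continue
            seen.add(id(st))
            open_ep = st["open"]
            episodes.append(ComponentEpisode(
                patient_id=patient_id, side=side,
                component_class=open_ep["component_class"],
                model_key=open_ep["model_key"], part_number=open_ep["part_number"],
                implant_date=open_ep["implant_date"],
                end_date=max(date, open_ep["implant_date"]), end_reason=reason,
                source_surgery_id=open_ep["surgery_id"],
                removal_surgery_id=rsid))
            for c in st["classes"]:
                in_situ.pop(c, None)

    for ev in timeline:
        date, ptype, sid = ev["date"], ev["procedure_type"], ev["surgery_id"]
        if ptype == "removal":
            close(set(in_situ), date, "removed", sid)
            continue
        if ptype == "revision" and not in_situ:
            rep.orphan_revisions += 1
            log.info("orphan revision %s for %s/%s", sid, patient_id, side)
        placed_classes: set = set()
        new_parts = []
        for part in ev["parts"]:
            cls_set = _classes_of(part)
            if cls_set & placed_classes:
                rep.duplicate_class_parts += 1
                log.info("duplicate %s part at surgery %s; keeping first",
                         part["component_class"], sid)
                continue
            placed_classes |= cls_set
            new_parts.append((part, cls_set))
        if placed_classes:
            close(placed_classes, date, "removed", sid)
        for part, cls_set in new_parts:
            st = {"classes": cls_set,
                  "open": {"component_class": part["component_class"],
                           "model_key": part["model_key"],
                           "part_number": part["part_number"],
                           "implant_date": date, "surgery_id": sid}}
            for c in cls_set:
                in_situ[c] = st

    # censor whatever is left in situ
    if death_date is not None and death_date <= study_end:
        cdate, creason = death_date, "censored_dead"
    else:
        cdate = last_encounter if last_encounter is not None else study_end
        cdate = min(cdate, study_end)
        creason = "censored_alive"
    close(set(in_situ), cdate, creason, None)
    for ep in episodes:
        if ep.end_reason.startswith("censored"):
            ep.removal_surgery_id = None
    return episodes


def link_episodes(typed: pd.DataFrame, mapping: pd.DataFrame,
                  encounters: pd.DataFrame, deaths: pd.DataFrame,
                  study_end: np.datetime64) -> tuple[pd.DataFrame, LinkageReport]:
    """Full linkage pass: timelines + removal inference for every patient-side.

    Returns an episodes table (one row per :class:`ComponentEpisode`) and the
    linkage accounting report.
    """
    rep = LinkageReport()
    timelines = build_timelines(typed, mapping, rep)
    last_enc: dict = {}
    if len(encounters):
        s = (encounters.assign(d=pd.to_datetime(encounters.encounter_date))
             .groupby("patient_id").d.max())
        last_enc = {k: np.datetime64(v.strftime("%Y-%m-%d"), "D") for k, v in s.items()}
    death = {}
    if len(deaths):
        for r in deaths.itertuples(index=False):
            death[r.patient_id] = np.datetime64(str(r.death_date)[:10], "D")

    all_eps: list[ComponentEpisode] = []
    for (pid, side), timeline in sorted(timelines.items()):
        all_eps.extend(infer_removals(
            timeline, last_enc.get(pid), death.get(pid), study_end, pid, side, rep))

    rows = [{
        "patient_id": e.patient_id, "side": e.side,
        "component_class": e.component_class, "model_key": e.model_key,
        "part_number": e.part_number,
        "implant_date": str(e.implant_date), "end_date": str(e.end_date),
        "end_reason": e.end_reason, "duration_days": e.duration_days,
        "source_surgery_id": e.source_surgery_id,
        "removal_surgery_id": e.removal_surgery_id,
    } for e in all_eps]
    cols = ["patient_id", "side", "component_class", "model_key", "part_number",
            "implant_date", "end_date", "end_reason", "duration_days",
            "source_surgery_id", "removal_surgery_id"]
    return pd.DataFrame(rows, columns=cols), rep
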