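"""Timeline construction and removal inference."""

import numpy as np
import pandas as pd
import pytest

from implantreg.linkage import (LinkageReport, build_timelines, infer_removals,
                                link_episodes)

STUDY_END = np.datetime64("2017-12-31")


def _part(cls, mk="M00001", pn=None, mono=False):
    return {"component_class": cls, "model_key": mk,
            "part_number": pn or f"{mk}-10", "is_monoblock": mono}


def _event(sid, date, ptype, parts):
    return {"surgery_id": sid, "date": np.datetime64(date, "D"),
            "procedure_type": ptype, "parts": parts}


def _primary_event(sid="s1", date="2010-01-01"):
    return _event(sid, date, "primary",
                  [_part("shell", "SH0001"), _part("liner", "LN0001"),
                   _part("stem", "ST0001"), _part("head", "HM0001")])


def by_class(episodes):
    return {(e.component_class, e.source_surgery_id): e for e in episodes}


class TestInferRemovals:
    def test_partial_revision_replaces_only_placed_classes(self):
        """New head + liner at revision remove prior head + liner; shell and
        stem stay at risk until censoring."""
        timeline = [
            _primary_event(),
            _event("s2", "2014-06-01", "revision",
                   [_part("head", "HM0002"), _part("liner", "LN0002")]),
        ]
        eps = infer_removals(timeline, np.datetime64("2016-05-01"), None,
                             STUDY_END, "P1", "left")
        d = by_class(eps)
        assert d[("head", "s1")].end_reason == "removed"
        assert d[("head", "s1")].end_date == np.datetime64("2014-06-01")
        assert d[("liner", "s1")].end_reason == "removed"
        assert d[("shell", "s1")].end_reason == "censored_alive"
        assert d[("shell", "s1")].end_date == np.datetime64("2016-05-01")
        assert d[("head", "s2")].end_reason == "censored_alive"
        assert len(eps) == 6

    def test_removal_coded_surgery_closes_everything(self):
        timeline = [_primary_event(),
                    _event("s2", "2016-03-15", "removal", [])]
        eps = infer_removals(timeline, np.datetime64("2017-01-01"), None,
                             STUDY_END, "P1", "left")
        assert len(eps) == 4
        assert all(e.end_reason == "removed" for e in eps)
        assert all(e.end_date == np.datetime64("2016-03-15") for e in eps)

    def test_censored_alive_at_last_encounter(self):
        eps = infer_removals([_primary_event()], np.datetime64("2017-06-01"),
                             None, STUDY_END, "P1", "left")
        assert len(eps) == 4
        assert all(e.end_reason == "censored_alive" for e in eps)
        assert all(e.end_date == np.datetime64("2017-06-01") for e in eps)

    def test_death_censors_with_dead_reason(self):
        eps = infer_removals([_primary_event()], np.datetime64("2015-06-01"),
                             np.datetime64("2015-08-01"), STUDY_END, "P1", "left")
        assert all(e.end_reason == "censored_dead" for e in eps)
        assert all(e.end_date == np.datetime64("2015-08-01") for e in eps)

    def test_monoblock_occupies_shell_and_head(self):
        """Replacing the head removes the monoblock; a new shell+head pair
        opens."""
        timeline = [
            _event("s1", "2010-01-01", "primary",
                   [_part("shell", "MB0001", mono=True), _part("stem", "ST0001")]),
            _event("s2", "2013-01-01", "revision",
                   [_part("head", "HM0001"), _part("shell", "SH0002")]),
        ]
        eps = infer_removals(timeline, np.datetime64("2015-01-01"), None,
                             STUDY_END, "P1", "left")
        d = by_class(eps)
        assert d[("shell", "s1")].end_reason == "removed"   # the monoblock
        assert d[("shell", "s1")].model_key == "MB0001"
        assert d[("stem", "s1")].end_reason == "censored_alive"
        assert d[("shell", "s2")].end_reason == "censored_alive"
        assert d[("head", "s2")].end_reason == "censored_alive"
        # the monoblock is a single episode spanning both classes
        assert len(eps) == 4

    def test_orphan_revision_opens_episodes(self):
        rep = LinkageReport()
        eps = infer_removals(
            [_event("s9", "2012-01-01", "revision", [_part("stem", "ST0009")])],
            np.datetime64("2014-01-01"), None, STUDY_END, "P1", "left", rep)
        assert rep.orphan_revisions == 1
        assert len(eps) == 1 and eps[0].end_reason == "censored_alive"

    def test_duplicate_class_part_keeps_first(self):
        rep = LinkageReport()
        eps = infer_removals(
            [_event("s1", "2010-01-01", "primary",
                    [_part("head", "HM0001"), _part("head", "HM0002")])],
            np.datetime64("2012-01-01"), None, STUDY_END, "P1", "left", rep)
        assert rep.duplicate_class_parts == 1
        assert len(eps) == 1 and eps[0].model_key == "HM0001"

    def test_revision_of_revision_chain(self):
        timeline = [
            _primary_event(),
            _event("s2", "2012-01-01", "revision", [_part("stem", "ST0002")]),
            _event("s3", "2015-01-01", "revision", [_part("stem", "ST0003")]),
        ]
        eps = infer_removals(timeline, np.datetime64("2016-01-01"), None,
                             STUDY_END, "P1", "left")
        d = by_class(eps)
        assert d[("stem", "s1")].end_date == np.datetime64("2012-01-01")
        assert d[("stem", "s2")].end_date == np.datetime64("2015-01-01")
        assert d[("stem", "s3")].end_reason == "censored_alive"

    def test_no_interval_overlap_within_class(self):
        timeline = [
            _primary_event(),
            _event("s2", "2011-05-01", "revision", [_part("head", "HM0002")]),
            _event("s3", "2014-07-01", "revision",
                   [_part("head", "HM0003"), _part("stem", "ST0002")]),
        ]
        eps = infer_removals(timeline, np.datetime64("2017-01-01"), None,
                             STUDY_END, "P1", "left")
        for cls in {"shell", "liner", "stem", "head"}:
            ivals = sorted((e.implant_date, e.end_date)
                           for e in eps if e.component_class == cls)
            for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
                assert b1 <= a2


class TestBuildTimelines:
    def _typed(self, rows):
        return pd.DataFrame(rows, columns=["surgery_id", "patient_id",
                                           "surgery_date", "procedure_type", "side"])

    def test_side_partition_and_ordering(self):
        typed = self._typed([
            ("a", "P1", "2015-01-01", "revision", "left"),
            ("b", "P1", "2010-01-01", "primary", "left"),
            ("c", "P1", "2012-01-01", "primary", "right"),
        ])
        tl = build_timelines(typed, pd.DataFrame())
        assert [e["surgery_id"] for e in tl[("P1", "left")]] == ["b", "a"]
        assert len(tl[("P1", "right")]) == 1

    def test_unknown_side_excluded_and_counted(self):
        rep = LinkageReport()
        typed = self._typed([("a", "P1", "2010-01-01", "primary", "unknown")])
        tl = build_timelines(typed, pd.DataFrame(), rep)
        assert tl == {} and rep.unknown_side_surgeries == 1

    def test_same_day_events_merge(self):
        rep = LinkageReport()
        typed = self._typed([
            ("a", "P1", "2010-01-01", "primary", "left"),
            ("b", "P1", "2010-01-01", "primary", "left"),
        ])
        tl = build_timelines(typed, pd.DataFrame(), rep)
        assert len(tl[("P1", "left")]) == 1 and rep.merged_same_day == 1


class TestAgainstGroundTruth:
    def test_removal_dates_exact_on_clean_cohort(self, clean_run):
        """With no noise and full observation, inferred removal dates equal
        ground-truth failure dates exactly."""
        eps = clean_run["episodes"]
        gt = clean_run["cohort"].gt_components
        gt_rem = gt[gt.true_end_reason.isin(["failed", "removed_incidental"])]
        pe = eps[eps.end_reason == "removed"]
        assert len(pe) == len(gt_rem)
        key = ["patient_id", "side", "component_class", "implant_date"]
        merged = gt_rem.merge(pe, on=key, suffixes=("_t", "_p"))
        assert len(merged) == len(gt_rem)
        assert (merged.true_end_date == merged.end_date).all()

    def test_each_component_one_episode(self, clean_run):
        eps = clean_run["episodes"]
        gt = clean_run["cohort"].gt_components
        assert len(eps) == len(gt)

    def test_out_of_system_inflates_survivorship(self):
        """Hiding revisions done elsewhere can only push the estimated curve
        up: same truth seed, higher out-of-system rate, higher S(10y)."""
        from implantreg.config import ErrorRates, SimulationConfig
        from implantreg.survival import km_from_episodes
        from conftest import run_pipeline

        s10 = {}
        for rate in (0.0, 0.3):
            sim = SimulationConfig(n_patients=1500, seed=13,
                                   error_rates=ErrorRates.zero(),
                                   out_of_system_revision_rate=rate)
            out = run_pipeline(sim)
            s10[rate] = km_from_episodes(out["episodes"]).survival_at(10 * 365.25)
        assert s10[0.3] > s10[0.0]
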