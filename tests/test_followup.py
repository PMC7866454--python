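"""Follow-up rules, event adjudication, person-period construction."""

import numpy as np
import pandas as pd
import pytest

from rxmsm.config import (
    AdjudicationConfig,
    EndpointCodes,
    FollowUpRules,
    PipelineConfig,
)
from rxmsm.followup import (
    adjudicate_ascvd,
    build_person_periods,
    derive_followup,
    first_endpoint,
)


def vl(*records):
    return pd.DataFrame([{"pid": p, "vl_day": d, "copies_per_ml": c}
                         for p, d, c in records],
                        columns=["pid", "vl_day", "copies_per_ml"])


def contacts(*records):
    return pd.DataFrame([{"pid": p, "day": d} for p, d in records],
                        columns=["pid", "day"])


def deaths(*records):
    return pd.DataFrame([{"pid": p, "death_day": d} for p, d in records],
                        columns=["pid", "death_day"])


ADMIN = 3000


class TestDeriveFollowup:
    def test_death_before_any_gap(self):
        fu = derive_followup(vl((0, 100, 20)),
                             contacts((0, 100), (0, 200), (0, 300)),
                             deaths((0, 350)), ADMIN)
        assert fu.iloc[0]["exit"] == 350
        assert fu.iloc[0]["exit_reason"] == "death"

    def test_long_gap_censors_at_last_contact(self):
        # regular visits, then the last contact 20 months before end of data
        c = contacts(*[(0, d) for d in range(100, ADMIN - 600, 90)],
                     (0, ADMIN - 600))
        fu = derive_followup(vl((0, 100, 20)), c, deaths(), ADMIN)
        assert fu.iloc[0]["exit"] == ADMIN - 600
        assert fu.iloc[0]["exit_reason"] == "gap_censor"

    def test_continuous_visits_admin_censored(self):
        c = contacts(*[(0, d) for d in range(100, ADMIN, 90)])
        fu = derive_followup(vl((0, 100, 20)), c, deaths(), ADMIN)
        assert fu.iloc[0]["exit"] == ADMIN
        assert fu.iloc[0]["exit_reason"] == "admin_censor"

    def test_internal_gap_censors_even_if_care_resumes(self):
        c = contacts((0, 100), (0, 200), (0, 700), (0, 800), (0, 2900))
        fu = derive_followup(vl((0, 100, 20)), c, deaths(), ADMIN)
        assert fu.iloc[0]["exit"] == 200
        assert fu.iloc[0]["exit_reason"] == "gap_censor"

    def test_death_during_incomplete_gap_wins(self):
        # death 5 months after the last contact: the 13-month gap never
        # completes, so the exit is the death
        fu = derive_followup(vl((0, 100, 20)), contacts((0, 100), (0, 200)),
                             deaths((0, 350)), ADMIN)
        assert fu.iloc[0]["exit_reason"] == "death"

    def test_never_suppressed_excluded(self):
        fu = derive_followup(vl((0, 100, 100000), (0, 200, 80000)),
                             contacts((0, 100)), deaths(), ADMIN)
        assert len(fu) == 0

    def test_entry_is_first_undetectable(self):
        c = contacts(*[(0, d) for d in range(100, ADMIN, 90)])
        fu = derive_followup(vl((0, 100, 100000), (0, 190, 20), (0, 280, 20)),
                             c, deaths(), ADMIN)
        assert fu.iloc[0]["entry"] == 190

    def test_gap_end_convention(self):
        rules = FollowUpRules(gap_censor_at="gap_end")
        fu = derive_followup(vl((0, 100, 20)), contacts((0, 100), (0, 200)),
                             deaths(), ADMIN, rules)
        assert fu.iloc[0]["exit"] == 200 + rules.gap_days


def cond(*records):
    return pd.DataFrame([{"pid": p, "code": c, "kind": k, "record_day": d}
                         for p, c, k, d in records],
                        columns=["pid", "code", "kind", "record_day"])


def labs(*records):
    return pd.DataFrame([{"pid": p, "analyte": a, "lab_day": d, "value": v}
                         for p, a, d, v in records],
                        columns=["pid", "analyte", "lab_day", "value"])


class TestAdjudication:
    def test_same_day_procedure_corroborates_coronary(self):
        ev = adjudicate_ascvd(cond((0, "icd_mi", "diagnosis", 100),
                                   (0, "ptca", "procedure", 100)), labs())
        assert list(ev["endpoint"]) == ["ascvd_coronary"]
        assert ev.iloc[0]["event_day"] == 100

    def test_uncorroborated_code_discarded(self):
        ev = adjudicate_ascvd(cond((0, "icd_mi", "diagnosis", 100)), labs())
        assert len(ev) == 0

    def test_neuroimaging_three_days_later_corroborates_stroke(self):
        ev = adjudicate_ascvd(cond((0, "icd_stroke", "diagnosis", 100),
                                   (0, "ct_head", "imaging", 103)), labs())
        assert list(ev["endpoint"]) == ["ascvd_cerebrovascular"]

    def test_evidence_outside_window_does_not_count(self):
        ev = adjudicate_ascvd(cond((0, "icd_mi", "diagnosis", 100),
                                   (0, "ptca", "procedure", 120)), labs())
        assert len(ev) == 0

    def test_biomarker_corroboration(self):
        ev = adjudicate_ascvd(cond((0, "icd_mi", "diagnosis", 100)),
                              labs((0, "troponin", 101, 0.8)))
        assert len(ev) == 1
        ev2 = adjudicate_ascvd(cond((0, "icd_mi", "diagnosis", 100)),
                               labs((0, "troponin", 101, 0.01)))
        assert len(ev2) == 0

    def test_earliest_corroborated_date_is_the_event(self):
        ev = adjudicate_ascvd(cond((0, "icd_mi", "diagnosis", 100),
                                   (0, "icd_mi", "diagnosis", 50),
                                   (0, "ptca", "procedure", 52),
                                   (0, "ptca", "procedure", 99)), labs())
        assert ev.iloc[0]["event_day"] == 50

    def test_removing_evidence_zeroes_events(self, small_cohort):
        from rxmsm.io import day_tables
        t = day_tables(small_cohort.tables)
        t["conditions"]["pid"] = t["conditions"]["patient_id"] - 1
        t["labs"]["pid"] = t["labs"]["patient_id"] - 1
        full = adjudicate_ascvd(t["conditions"], t["labs"])
        assert len(full) > 0
        stripped = t["conditions"][t["conditions"]["kind"] == "diagnosis"]
        no_labs = t["labs"][t["labs"]["analyte"] != "troponin"]
        none = adjudicate_ascvd(stripped, no_labs)
        assert len(none) == 0

    def test_missing_config_rejected(self):
        with pytest.raises(ValueError):
            adjudicate_ascvd(cond(), labs(), None)


class TestFirstEndpoint:
    codes = EndpointCodes(include=frozenset({"icd_pneumonia"}),
                          exclude=frozenset({"icd_cellulitis"}))

    def test_only_excluded_code_gives_none(self):
        entry = pd.Series([10], index=[0])
        s = first_endpoint(cond((0, "icd_cellulitis", "diagnosis", 100)),
                           self.codes, entry)
        assert 0 not in s.index

    def test_excluded_then_qualifying(self):
        entry = pd.Series([10], index=[0])
        s = first_endpoint(cond((0, "icd_cellulitis", "diagnosis", 50),
                                (0, "icd_pneumonia", "diagnosis", 80)),
                           self.codes, entry)
        assert s.loc[0] == 80

    def test_no_records_gives_none(self):
        s = first_endpoint(cond(), self.codes, pd.Series([10], index=[0]))
        assert len(s) == 0

    def test_code_before_entry_ignored(self):
        entry = pd.Series([100], index=[0])
        s = first_endpoint(cond((0, "icd_pneumonia", "diagnosis", 90)),
                           self.codes, entry)
        assert 0 not in s.index


def fu_frame(*rows):
    return pd.DataFrame(rows, columns=["pid", "entry", "exit", "exit_reason"])


class TestPersonPeriods:
    def test_one_year_weekly_gives_53_periods(self):
        fu = fu_frame((0, 0, 365, "admin_censor"))
        pp = build_person_periods(fu, pd.DataFrame(columns=["pid", "endpoint",
                                                            "event_day"]),
                                  "death")
        assert len(pp) == 53
        assert not pp["event"].any()

    def test_death_midweek_truncates_final_period(self):
        fu = fu_frame((0, 0, 10, "death"))
        pp = build_person_periods(fu, pd.DataFrame(columns=["pid", "endpoint",
                                                            "event_day"]),
                                  "death")
        assert pp["stop"].iloc[-1] == 10
        assert pp["event"].iloc[-1]
        assert pp["event"].sum() == 1

    def test_event_on_anchor_belongs_to_period_ending_there(self):
        fu = fu_frame((0, 0, 14, "death"))
        pp = build_person_periods(fu, pd.DataFrame(columns=["pid", "endpoint",
                                                            "event_day"]),
                                  "death")
        assert list(pp["stop"]) == [7, 14]
        assert list(pp["event"]) == [False, True]

    def test_person_time_conserved(self, small_result):
        fu = small_result.context.followup
        pp = small_result.periods["death"]
        per_patient = pp.groupby("pid")["ptime"].sum()
        expected = (fu.set_index("pid")["exit"] - fu.set_index("pid")["entry"])
        assert np.array_equal(per_patient.sort_index().to_numpy(),
                              expected.sort_index().to_numpy())

    def test_explanatory_endpoint_truncates_at_event(self):
        fu = fu_frame((0, 0, 365, "admin_censor"))
        ev = pd.DataFrame([{"pid": 0, "endpoint": "infection",
                            "event_day": 100}])
        pp = build_person_periods(fu, ev, "infection")
        assert pp["stop"].iloc[-1] == 100
        assert pp["event"].iloc[-1]

    def test_events_conserved_on_cohort(self, small_result):
        ctx = small_result.context
        cfg = PipelineConfig()
        for ep in ("infection", "cancer"):
            ev = ctx.events[ctx.events["endpoint"] == ep]
            pp = build_person_periods(ctx.followup, ctx.events, ep)
            assert pp["event"].sum() == len(ev)
            flagged = pp[pp["event"]].groupby("pid").size()
            assert (flagged == 1).all()
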