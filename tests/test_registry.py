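from datetime import date

import pytest

from accessmon.geodata import Clinic, Village
from accessmon.registry import (PatientEvent, PatientRecord, PeriodSpec,
                                RegistryError, Timeline, active_cohort,
                                link_villages, quarterly_counts,
                                read_register, write_register)

D = date


def _village(vid, name):
    return Village(village_id=vid, name=name, x=0.0, y=0.0,
                   population_weight=1.0)


def _clinic(cid, opening):
    return Clinic(clinic_id=cid, name=cid, x=0.0, y=0.0,
                  opening_date=opening)


def _patient(pid, start, clinic="C1", events=(), village="V1"):
    return PatientRecord(patient_id=pid, village_text="v", clinic_id=clinic,
                         art_start_date=start, events=list(events),
                         village_id=village)


@pytest.fixture
def timeline():
    return Timeline(
        clinics=[_clinic("C1", D(2005, 7, 1)), _clinic("C2", D(2006, 9, 1))],
        study_start=D(2005, 7, 1), study_end=D(2007, 6, 30),
    )


class TestLinkVillages:
    GAZ = [_village("V1", "chilumba"), _village("V2", "Kaporo")]

    def _rec(self, text):
        return PatientRecord(patient_id="P1", village_text=text,
                             clinic_id="C1", art_start_date=D(2006, 1, 1))

    def test_normalised_exact_match(self):
        linked, report = link_villages([self._rec("  Chilumba ")], self.GAZ)
        assert linked[0].village_id == "V1"
        assert report.matched_fraction == 1.0

    def test_alias_table_match(self):
        linked, _ = link_villages([self._rec("Kaporo trading")], self.GAZ,
                                  aliases={"Kaporo Trading": "V2"})
        assert linked[0].village_id == "V2"

    def test_unmatched_is_reported_not_raised(self):
        linked, report = link_villages([self._rec("xyzzy")], self.GAZ)
        assert linked[0].village_id is None
        assert report.unmatched_texts == ["xyzzy"]
        assert report.n_matched == 0

    def test_duplicate_gazetteer_names_rejected(self):
        gaz = [_village("V1", "Alpha"), _village("V2", " alpha ")]
        with pytest.raises(RegistryError, match="unique"):
            link_villages([self._rec("Alpha")], gaz)


class TestPatientRecord:
    def test_transfer_out_alone_ends_followup(self):
        rec = _patient("P1", D(2006, 1, 1), events=[
            PatientEvent(D(2006, 6, 1), "transfer_out")])
        assert rec.active_at(D(2006, 5, 1))
        assert rec.active_at(D(2006, 6, 1))  # not strictly before
        assert not rec.active_at(D(2006, 6, 2))

    def test_transfer_pair_keeps_patient_active_at_new_clinic(self):
        rec = _patient("P1", D(2006, 1, 1), clinic="C1", events=[
            PatientEvent(D(2006, 6, 1), "transfer_out"),
            PatientEvent(D(2006, 6, 1), "transfer_in", clinic_id="C2")])
        assert rec.active_at(D(2007, 1, 1))
        assert rec.clinic_at(D(2007, 1, 1)) == "C2"
        assert rec.clinic_at(D(2006, 6, 1), before=True) == "C1"

    def test_two_terminal_events_rejected(self):
        with pytest.raises(RegistryError, match="terminal"):
            _patient("P1", D(2006, 1, 1), events=[
                PatientEvent(D(2006, 2, 1), "died"),
                PatientEvent(D(2006, 3, 1), "lost")])

    def test_event_before_start_rejected(self):
        with pytest.raises(RegistryError, match="before ART start"):
            _patient("P1", D(2006, 1, 1), events=[
                PatientEvent(D(2005, 12, 1), "lost")])


class TestActiveCohort:
    def test_start_and_exit_rules(self, timeline):
        records = [
            _patient("after", D(2006, 7, 1)),
            _patient("out_daybefore", D(2006, 1, 1), events=[
                PatientEvent(D(2006, 5, 31), "transfer_out")]),
            _patient("steady", D(2006, 1, 1)),
            _patient("unlinked", D(2006, 1, 1), village=None),
        ]
        cohort = active_cohort(records, timeline, D(2006, 6, 1))
        assert list(cohort.patient_id) == ["steady"]

    def test_roster_matches_direct_enumeration(self, timeline):
        # 100 patients with scripted events; compare to a hand enumeration
        import numpy as np
        rng = np.random.default_rng(3)
        records = []
        for i in range(100):
            start = D(2005 + int(rng.integers(0, 2)),
                      int(rng.integers(1, 13)), int(rng.integers(1, 28)))
            if start < D(2005, 7, 1):
                start = D(2005, 7, 1)
            events = []
            if rng.random() < 0.3:
                ev_day = start.toordinal() + int(rng.integers(30, 300))
                events.append(PatientEvent(D.fromordinal(ev_day), "lost"))
            records.append(_patient(f"P{i:03d}", start, events=events))
        at = D(2006, 10, 1)
        cohort = active_cohort(records, timeline, at)
        expected = {
            r.patient_id for r in records
            if r.art_start_date <= at and not any(
                e.event_date < at for e in r.events)
        }
        assert set(cohort.patient_id) == expected


class TestQuarterlyCounts:
    def test_empty_register_all_zero(self, timeline):
        tbl = quarterly_counts([], timeline)
        assert (tbl.starts == 0).all() and (tbl.transfers_out == 0).all()
        assert len(tbl) == 8 * 2  # 8 quarters x 2 clinics

    def test_start_and_transfer_in_right_quarters(self, timeline):
        rec = _patient("P1", D(2005, 8, 10), clinic="C1", events=[
            PatientEvent(D(2006, 10, 5), "transfer_out"),
            PatientEvent(D(2006, 10, 5), "transfer_in", clinic_id="C2")])
        tbl = quarterly_counts([rec], timeline).set_index(
            ["quarter", "clinic_id"])
        assert tbl.loc[("2005Q3", "C1"), "starts"] == 1
        assert tbl.loc[("2006Q4", "C1"), "transfers_out"] == 1
        assert tbl.starts.sum() == 1
        assert tbl.transfers_out.sum() == 1

    def test_transfer_in_patients_excluded_from_starts(self, timeline):
        rec = _patient("P1", D(2005, 8, 10), clinic="C1", events=[
            PatientEvent(D(2006, 10, 5), "transfer_in", clinic_id="C2")])
        tbl = quarterly_counts([rec], timeline)
        assert tbl.starts.sum() == 0

    def test_total_starts_equals_unique_non_transfer_in(self, district):
        tbl = quarterly_counts(district.records, district.timeline)
        expected = sum(1 for r in district.records if not r.transferred_in)
        assert tbl.starts.sum() == expected

    def test_transfer_spike_in_opening_quarter(self, district):
        # clinics open in 2006Q3 and 2008Q1: transfers out must jump in
        # the opening quarter relative to the quarter before it
        tbl = quarterly_counts(district.records, district.timeline)
        per_q = tbl.groupby("quarter").transfers_out.sum()
        for before, opening in (("2006Q2", "2006Q3"), ("2007Q4", "2008Q1")):
            assert per_q[opening] > per_q[before]


class TestRegisterIO:
    def test_roundtrip(self, tmp_path, timeline):
        records = [
            _patient("P1", D(2006, 1, 1), events=[
                PatientEvent(D(2006, 6, 1), "transfer_out"),
                PatientEvent(D(2006, 6, 1), "transfer_in", clinic_id="C2"),
            ]),
            _patient("P2", D(2006, 2, 1), events=[
                PatientEvent(D(2006, 9, 1), "died")]),
        ]
        p = tmp_path / "reg.csv"
        write_register(records, p)
        back = read_register(p)
        assert {r.patient_id for r in back} == {"P1", "P2"}
        p1 = next(r for r in back if r.patient_id == "P1")
        assert p1.clinic_at(D(2007, 1, 1)) == "C2"
        assert [e.event_type for e in p1.events] == ["transfer_out",
                                                     "transfer_in"]

    def test_orphan_events_rejected(self, tmp_path):
        p = tmp_path / "reg.csv"
        p.write_text("patient_id,village_text,clinic_id,art_start_date,"
                     "event_type,event_date\n"
                     "P9,v,C1,2006-01-01,died,2006-05-01\n")
        with pytest.raises(RegistryError, match="no start row"):
            read_register(p)


class TestTimeline:
    def test_quarters_contiguous_nonoverlapping(self, timeline):
        qs = timeline.quarters()
        assert qs[0][1] == D(2005, 7, 1)
        for (_, _, end), (_, nxt, _) in zip(qs, qs[1:]):
            assert (nxt - end).days == 1

    def test_period_validation(self):
        with pytest.raises(RegistryError):
            PeriodSpec("bad", D(2006, 1, 1), D(2006, 1, 1))
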