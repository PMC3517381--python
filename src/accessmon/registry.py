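"""Patient register ingest, village linkage and cohort accounting.

Registers arrive as long-format CSV: one ``start`` row per patient plus
one row per subsequent event (``transfer_out``, ``transfer_in``, ``died``,
``lost``, ``stop``). Village of residence is free text and is linked to
the coded village gazetteer by normalised exact match, with a curated
alias table as the escape hatch; unmatched villages are a reported state,
never an error, and are excluded from travel-time analyses with explicit
accounting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from .geodata import Clinic, Village, _parse_date

TERMINAL_EVENTS = {"died", "lost", "stop"}
EVENT_TYPES = TERMINAL_EVENTS | {"transfer_out", "transfer_in", "start"}


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class PatientEvent:
    event_date: date
    event_type: str
    clinic_id: str | None = None  # destination clinic for transfer_in


@dataclass
class PatientRecord:
    patient_id: str
    village_text: str
    clinic_id: str  # clinic where ART was started
    art_start_date: date
    events: list[PatientEvent] = field(default_factory=list)
    village_id: str | None = None

    def __post_init__(self) -> None:
        terminal = [e for e in self.events if e.event_type in TERMINAL_EVENTS]
        if len(terminal) > 1:
            raise RegistryError(
                f"patient {self.patient_id}: more than one terminal event"
            )
        for e in self.events:
            if e.event_type not in EVENT_TYPES - {"start"}:
                raise RegistryError(
                    f"patient {self.patient_id}: unknown event type "
                    f"{e.event_type!r}"
                )
            if e.event_date < self.art_start_date:
                raise RegistryError(
                    f"patient {self.patient_id}: event before ART start"
                )

    @property
    def transferred_in(self) -> bool:
        """True if the patient arrived from outside: a transfer_in with
        no in-register transfer_out on or before the same date. Paired
        out/in rows for in-district moves do not count."""
        out_dates = [e.event_date for e in self.events
                     if e.event_type == "transfer_out"]
        return any(
            e.event_type == "transfer_in"
            and not any(d <= e.event_date for d in out_dates)
            for e in self.events
        )

    def clinic_at(self, at_date: date, *, before: bool = False) -> str:
        """Clinic in effect at a date: last transfer_in on/before it
        (strictly before with ``before=True``), else the starting
        clinic."""
        current = self.clinic_id
        for e in sorted(self.events, key=lambda e: e.event_date):
            hit = (e.event_date < at_date if before
                   else e.event_date <= at_date)
            if e.event_type == "transfer_in" and hit:
                current = e.clinic_id or current
        return current

    def exit_date(self) -> date | None:
        """Date follow-up in the district ends, if it does.

        A died/lost/stop event ends it outright; a transfer_out ends it
        unless a later (or same-day) transfer_in shows the patient
        resumed care at another district clinic.
        """
        exit_: date | None = None
        for e in sorted(self.events, key=lambda e: e.event_date):
            if e.event_type in TERMINAL_EVENTS:
                return e.event_date if exit_ is None else min(exit_, e.event_date)
            if e.event_type == "transfer_out":
                exit_ = e.event_date
            elif e.event_type == "transfer_in":
                exit_ = None
        return exit_

    def active_at(self, at_date: date) -> bool:
        """On ART in the district at a date: started on/before it, and
        follow-up has not ended strictly before it."""
        if self.art_start_date > at_date:
            return False
        exit_ = self.exit_date()
        return exit_ is None or exit_ >= at_date


@dataclass(frozen=True)
class PeriodSpec:
    label: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise RegistryError(
                f"period {self.label}: start must precede end"
            )


def _quarter_start(d: date) -> date:
    return date(d.year, 3 * ((d.month - 1) // 3) + 1, 1)


def _next_quarter(d: date) -> date:
    m = d.month + 3
    return date(d.year + (m - 1) // 12, (m - 1) % 12 + 1, 1)


@dataclass
class Timeline:
    """Clinic openings plus calendar-quarter boundaries for the study
    window."""

    clinics: list[Clinic]
    study_start: date
    study_end: date

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise RegistryError("study_start must precede study_end")

    def open_clinics(self, at_date: date) -> list[Clinic]:
        return [c for c in self.clinics if c.opening_date <= at_date]

    def quarters(self) -> list[tuple[str, date, date]]:
        """Contiguous calendar quarters (label, first day, last day)
        covering the study window."""
        out = []
        q = _quarter_start(self.study_start)
        while q <= self.study_end:
            nxt = _next_quarter(q)
            label = f"{q.year}Q{(q.month - 1) // 3 + 1}"
            out.append((label, q, nxt - timedelta(days=1)))
            q = nxt
        return out


def read_register(path: str | Path) -> list[PatientRecord]:
    """Read a long-format register CSV.

    Columns: ``patient_id, village_text, clinic_id, art_start_date,
    event_type, event_date``. Every patient must have exactly one
    ``start`` row; other rows add events.
    """
    starts: dict[str, PatientRecord] = {}
    pending: dict[str, list[PatientEvent]] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            pid = row["patient_id"]
            etype = row["event_type"].strip()
            edate = _parse_date(row["event_date"])
            if etype == "start":
                if pid in starts:
                    raise RegistryError(
                        f"row {i}: duplicate start row for patient {pid}"
                    )
                starts[pid] = PatientRecord(
                    patient_id=pid,
                    village_text=row["village_text"],
                    clinic_id=row["clinic_id"],
                    art_start_date=edate,
                )
            else:
                pending.setdefault(pid, []).append(
                    PatientEvent(event_date=edate, event_type=etype,
                                 clinic_id=row.get("clinic_id") or None)
                )
    records = []
    for pid, rec in starts.items():
        evts = sorted(pending.pop(pid, []), key=lambda e: e.event_date)
        records.append(replace(rec, events=evts))
    if pending:
        raise RegistryError(
            f"events for patients with no start row: {sorted(pending)}"
        )
    return records


def write_register(records: list[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "village_text", "clinic_id",
                    "art_start_date", "event_type", "event_date"])
        for r in records:
            w.writerow([r.patient_id, r.village_text, r.clinic_id,
                        r.art_start_date.isoformat(), "start",
                        r.art_start_date.isoformat()])
            for e in r.events:
                w.writerow([r.patient_id, r.village_text, e.clinic_id or "",
                            r.art_start_date.isoformat(), e.event_type,
                            e.event_date.isoformat()])


def normalise(text: str) -> str:
    return " ".join(text.casefold().split())


@dataclass
class LinkReport:
    n_total: int
    n_matched: int
    unmatched_texts: list[str]

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n_total if self.n_total else 1.0

    def summary(self) -> str:
        return (f"linked {self.n_matched}/{self.n_total} records "
                f"({100 * self.matched_fraction:.1f}%); "
                f"{len(self.unmatched_texts)} distinct unmatched texts")


def read_aliases(path: str | Path) -> dict[str, str]:
    """Alias CSV: columns ``village_text, village_id``."""
    aliases = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            aliases[normalise(row["village_text"])] = row["village_id"]
    return aliases


def link_villages(records: list[PatientRecord], gazetteer: list[Village],
                  aliases: dict[str, str] | None = None,
                  ) -> tuple[list[PatientRecord], LinkReport]:
    """Link free-text villages to the coded gazetteer.

    Normalised exact name match first (case-fold, trim, collapse internal
    whitespace), then the alias table. Unmatched records keep
    ``village_id=None`` and are listed in the report.
    """
    by_name: dict[str, str] = {}
    for v in gazetteer:
        key = normalise(v.name)
        if key in by_name:
            raise RegistryError(
                f"gazetteer names not unique after normalisation: {key!r}"
            )
        by_name[key] = v.village_id
    alias_map = {normalise(k): vid for k, vid in (aliases or {}).items()}
    valid_ids = {v.village_id for v in gazetteer}
    linked = []
    unmatched: list[str] = []
    n_matched = 0
    for rec in records:
        key = normalise(rec.village_text)
        vid = by_name.get(key) or alias_map.get(key)
        if vid is not None and vid in valid_ids:
            linked.append(replace(rec, village_id=vid))
            n_matched += 1
        else:
            linked.append(replace(rec, village_id=None))
            if rec.village_text not in unmatched:
                unmatched.append(rec.village_text)
    report = LinkReport(n_total=len(records), n_matched=n_matched,
                        unmatched_texts=unmatched)
    return linked, report


def active_cohort(records: list[PatientRecord], timeline: Timeline,
                  at_date: date) -> pd.DataFrame:
    """Patients on ART at a date, with their current clinic and village.

    Included iff ART start <= date and no terminal event strictly before
    the date. Unlinked patients (no village_id) are excluded.
    """
    rows = [
        (r.patient_id, r.clinic_at(at_date), r.village_id)
        for r in records
        if r.active_at(at_date) and r.village_id is not None
    ]
    return pd.DataFrame(rows, columns=["patient_id", "clinic_id",
                                       "village_id"])


def quarterly_counts(records: list[PatientRecord],
                     timeline: Timeline) -> pd.DataFrame:
    """Starts and transfers out per clinic per calendar quarter.

    Starts count each patient once in the quarter of their ART start, at
    the starting clinic, excluding patients who ever transferred in from
    another clinic; transfers out are counted by event date at the clinic
    the patient was attending when the transfer happened.
    """
    quarters = timeline.quarters()
    clinic_ids = [c.clinic_id for c in timeline.clinics]
    rows = []
    for label, q0, q1 in quarters:
        starts = {cid: 0 for cid in clinic_ids}
        transfers = {cid: 0 for cid in clinic_ids}
        for r in records:
            if (not r.transferred_in and q0 <= r.art_start_date <= q1
                    and r.clinic_id in starts):
                starts[r.clinic_id] += 1
            for e in r.events:
                if e.event_type == "transfer_out" and q0 <= e.event_date <= q1:
                    # attribute the transfer to the clinic being left, so a
                    # same-day transfer_in must not already switch it
                    cid = r.clinic_at(e.event_date, before=True)
                    if cid in transfers:
                        transfers[cid] += 1
        for cid in clinic_ids:
            rows.append((label, cid, starts[cid], transfers[cid]))
    return pd.DataFrame(rows, columns=["quarter", "clinic_id", "starts",
                                       "transfers_out"])
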