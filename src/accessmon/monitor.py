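"""Headline monitoring metrics: potential vs actual travel time.

Potential travel time (PTT) is the travel time from a person's village to
the nearest *open* clinic; actual travel time (ATT) is the time to the
clinic actually attended, so ATT >= PTT by construction and the gap is
the monitoring signal for patients bypassing their nearest service.

Patient-level medians are unweighted (each patient counts once);
population-level summaries weight villages by census population size.
Confidence intervals for medians use the percentile bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .costdistance import cumulative_cost, village_travel_times
from .friction import FrictionSurface
from .geodata import Clinic, Village
from .registry import PatientRecord, Timeline, active_cohort

log = logging.getLogger(__name__)

_TIE_TOL = 1e-9


class MonitorError(ValueError):
    pass


class ClinicTravelTimes:
    """Cache of village-to-clinic travel times over one friction surface.

    One single-source cost-distance solve per clinic; the cell graph is
    undirected, so the field from the clinic gives the village-to-clinic
    time for every village at once.
    """

    def __init__(self, friction: FrictionSurface, clinics: list[Clinic],
                 villages: list[Village]):
        self.clinics = {c.clinic_id: c for c in clinics}
        self.villages = {v.village_id: v for v in villages}
        self._minutes: dict[str, dict[str, float]] = {}
        for c in clinics:
            fld = cumulative_cost(friction, [c])
            tbl = village_travel_times(fld, villages)
            self._minutes[c.clinic_id] = dict(
                zip(tbl["village_id"], tbl["minutes"])
            )

    def minutes(self, village_id: str, clinic_id: str) -> float:
        return self._minutes[clinic_id][village_id]

    def nearest(self, village_id: str,
                open_ids: list[str]) -> tuple[str, float]:
        """Nearest open clinic and its travel time; ties (within 1e-9)
        broken by lowest clinic_id."""
        times = {cid: self._minutes[cid][village_id] for cid in open_ids}
        best = min(times.values())
        nearest_id = min(cid for cid, t in times.items()
                         if t <= best + _TIE_TOL)
        return nearest_id, best


@dataclass
class AccessSnapshot:
    """Per-patient and per-village access metrics at one date."""

    snapshot_date: date
    patients: pd.DataFrame  # patient_id, village_id, clinic_id,
    #                         nearest_clinic_id, actual_minutes,
    #                         potential_minutes, attends_nearest
    population: pd.DataFrame  # village_id, weight, potential_minutes

    @property
    def bypass_proportion(self) -> float:
        n = len(self.patients)
        return float((~self.patients["attends_nearest"]).sum() / n) if n else 0.0


def snapshot(records: list[PatientRecord], villages: list[Village],
             clinics: list[Clinic], timeline: Timeline,
             friction: FrictionSurface, at_date: date,
             travel: ClinicTravelTimes | None = None) -> AccessSnapshot:
    """Access snapshot at a date: PTT/ATT per active patient and PTT per
    village for the general population.

    Raises if no clinic is open or if a patient attends a clinic that has
    not yet opened at the snapshot date.
    """
    open_clinics = timeline.open_clinics(at_date)
    if not open_clinics:
        raise MonitorError(f"no clinic open at {at_date}")
    open_ids = sorted(c.clinic_id for c in open_clinics)
    if travel is None:
        travel = ClinicTravelTimes(friction, clinics, villages)
    cohort = active_cohort(records, timeline, at_date)
    rows = []
    for pid, cid, vid in cohort.itertuples(index=False):
        if cid not in open_ids:
            raise MonitorError(
                f"patient {pid} attends clinic {cid}, not open at {at_date}"
            )
        nearest_id, potential = travel.nearest(vid, open_ids)
        actual = travel.minutes(vid, cid)
        rows.append((pid, vid, cid, nearest_id, actual, potential,
                     actual <= potential + _TIE_TOL))
    patients = pd.DataFrame(
        rows, columns=["patient_id", "village_id", "clinic_id",
                       "nearest_clinic_id", "actual_minutes",
                       "potential_minutes", "attends_nearest"],
    )
    pop_rows = [
        (v.village_id, v.population_weight,
         travel.nearest(v.village_id, open_ids)[1])
        for v in villages
    ]
    population = pd.DataFrame(
        pop_rows, columns=["village_id", "weight", "potential_minutes"]
    )
    return AccessSnapshot(snapshot_date=at_date, patients=patients,
                          population=population)


def period_entry_snapshot(records: list[PatientRecord],
                          villages: list[Village], clinics: list[Clinic],
                          timeline: Timeline, friction: FrictionSurface,
                          period_start: date, period_end: date,
                          travel: ClinicTravelTimes | None = None
                          ) -> AccessSnapshot:
    """Snapshot for a study period, evaluated per patient at their entry.

    A patient enters the period at its start, or at ART start if that is
    later; exposure (attending the nearest open clinic or not) is judged
    against the clinics open at that entry date. Patients who exited
    before the period or started after it are excluded.
    """
    if travel is None:
        travel = ClinicTravelTimes(friction, clinics, villages)
    rows = []
    for rec in records:
        if rec.village_id is None or rec.art_start_date > period_end:
            continue
        entry = max(period_start, rec.art_start_date)
        if not rec.active_at(entry):
            continue
        cid = rec.clinic_at(entry)
        open_ids = sorted(c.clinic_id
                          for c in timeline.open_clinics(entry))
        if not open_ids:
            continue
        if cid not in open_ids:
            raise MonitorError(
                f"patient {rec.patient_id} attends clinic {cid}, not open "
                f"at {entry}"
            )
        nearest_id, potential = travel.nearest(rec.village_id, open_ids)
        actual = travel.minutes(rec.village_id, cid)
        rows.append((rec.patient_id, rec.village_id, cid, nearest_id,
                     actual, potential, actual <= potential + _TIE_TOL))
    patients = pd.DataFrame(
        rows, columns=["patient_id", "village_id", "clinic_id",
                       "nearest_clinic_id", "actual_minutes",
                       "potential_minutes", "attends_nearest"],
    )
    population = pd.DataFrame(
        [(v.village_id, v.population_weight, np.nan) for v in villages],
        columns=["village_id", "weight", "potential_minutes"],
    )
    return AccessSnapshot(snapshot_date=period_start, patients=patients,
                          population=population)


def weighted_quantile(values, weights, q: float) -> float:
    """Smallest value whose cumulative normalised weight reaches q.

    Weights must be nonnegative with positive sum; zero-weight values
    never pull the quantile.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise MonitorError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise MonitorError("sum of weights must be positive")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order]) / total
    idx = np.searchsorted(cum, q, side="left")
    idx = min(idx, len(values) - 1)
    return float(values[order][idx])


def bootstrap_median_ci(values, B: int = 1000, seed: int | None = None,
                        level: float = 0.95,
                        weights=None) -> tuple[float, float]:
    """Percentile bootstrap CI for the median.

    With ``weights``, resamples observations with probability
    proportional to weight (population summaries); otherwise plain
    resampling with replacement.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0 or B < 1:
        raise MonitorError("need at least one value and one replicate")
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        p = weights / weights.sum()
    idx = rng.choice(n, size=(B, n), replace=True, p=p)
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class WeightedSummary:
    median: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float
    n: int
    total_weight: float


def weighted_summary(values, weights, B: int = 1000,
                     seed: int | None = None,
                     level: float = 0.95) -> WeightedSummary:
    """Weighted median and quartiles with a bootstrap CI for the median."""
    median = weighted_quantile(values, weights, 0.5)
    q1 = weighted_quantile(values, weights, 0.25)
    q3 = weighted_quantile(values, weights, 0.75)
    lo, hi = bootstrap_median_ci(values, B=B, seed=seed, level=level,
                                 weights=weights)
    return WeightedSummary(median=median, q1=q1, q3=q3,
                           ci_low=min(lo, median), ci_high=max(hi, median),
                           n=len(np.asarray(values)),
                           total_weight=float(np.sum(weights)))


def bypass_series(snapshots: list[AccessSnapshot]) -> pd.DataFrame:
    """Proportion of patients not attending their nearest clinic, per
    snapshot."""
    if not snapshots:
        raise MonitorError("no snapshots given")
    rows = [(s.snapshot_date, s.bypass_proportion, len(s.patients))
            for s in snapshots]
    return pd.DataFrame(rows, columns=["date", "bypass_proportion", "n"])


def timeseries(records: list[PatientRecord], villages: list[Village],
               clinics: list[Clinic], timeline: Timeline,
               friction: FrictionSurface, B: int = 1000,
               seed: int | None = None) -> pd.DataFrame:
    """Quarterly monitoring series over the study window.

    Snapshots are taken at the end of each calendar quarter with at least
    one open clinic. Patient PTT/ATT medians are unweighted with
    percentile-bootstrap CIs; the population PTT summary weights villages
    by census size.
    """
    travel = ClinicTravelTimes(friction, clinics, villages)
    ss = np.random.SeedSequence(seed)
    rows = []
    for label, _q0, q1 in timeline.quarters():
        if not timeline.open_clinics(q1):
            continue
        snap = snapshot(records, villages, clinics, timeline, friction,
                        q1, travel=travel)
        seeds = ss.spawn(3)
        pat = snap.patients
        pop = snap.population
        pop_sum = weighted_summary(pop["potential_minutes"], pop["weight"],
                                   B=B, seed=seeds[0], level=0.95)
        row = {
            "quarter": label,
            "date": q1,
            "n_patients": len(pat),
            "n_open_clinics": len(timeline.open_clinics(q1)),
            "bypass_proportion": snap.bypass_proportion,
            "pop_ptt_median": pop_sum.median,
            "pop_ptt_q1": pop_sum.q1,
            "pop_ptt_q3": pop_sum.q3,
            "pop_ptt_ci_low": pop_sum.ci_low,
            "pop_ptt_ci_high": pop_sum.ci_high,
        }
        if len(pat):
            ptt = pat["potential_minutes"].to_numpy()
            att = pat["actual_minutes"].to_numpy()
            row["ptt_median"] = float(np.median(ptt))
            row["att_median"] = float(np.median(att))
            row["ptt_ci_low"], row["ptt_ci_high"] = bootstrap_median_ci(
                ptt, B=B, seed=seeds[1])
            row["att_ci_low"], row["att_ci_high"] = bootstrap_median_ci(
                att, B=B, seed=seeds[2])
        else:
            for k in ("ptt_median", "att_median", "ptt_ci_low",
                      "ptt_ci_high", "att_ci_low", "att_ci_high"):
                row[k] = np.nan
        rows.append(row)
        log.info("quarter %s: %d patients, bypass %.3f", label,
                 row["n_patients"], row["bypass_proportion"])
    return pd.DataFrame(rows)
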