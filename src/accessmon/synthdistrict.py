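"""Seeded synthetic district generator with known ground truth.

Emulates a lakeshore-like rural district: one north-south tarmac trunk
road, feeder tracks branching off it, villages clustered near the trunk
with census-style log-normal population weights, and 2-4 clinics opening
sequentially along the road. A patient cohort is simulated month by
month: initiation follows a logistic distance-decay in potential travel
time, clinic choice mixes nearest-clinic attendance with a preference for
the longest-standing clinic (the district-hospital effect), and patients
attending a non-nearest clinic face a monthly hazard of transferring once
a nearer clinic is available.

All randomness flows through a single generator stream seeded from the
config, in a fixed draw order, so a fixed seed reproduces every output
file byte for byte.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .costdistance import cumulative_cost, village_travel_times
from .friction import SpeedSet, build_friction
from .geodata import (Clinic, GridSpec, RoadNetwork, RoadSegment, Village,
                      rasterize_roads, write_clinics, write_roads,
                      write_villages)
from .registry import (PatientEvent, PatientRecord, PeriodSpec, Timeline,
                       write_register)


class ScenarioError(ValueError):
    pass


def _add_months(d: date, months: int) -> date:
    m = d.month - 1 + months
    return date(d.year + m // 12, m % 12 + 1, d.day)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic district and cohort.

    The default scenario mirrors the shape of a four-clinic roll-out:
    clinics opening at months 0, 14, 31 and 31 of a 49-month study
    window, ~150 villages strung along a trunk road.
    """

    seed: int = 20050701
    # grid: 12 km (east-west) x 30 km (north-south) at 100 m
    cell_size: float = 100.0
    n_rows: int = 300
    n_cols: int = 120
    origin_x: float = 0.0
    origin_y: float = 30_000.0
    trunk_x: float = 8_000.0  # lakeshore trunk road, east of centre
    n_feeder_tracks: int = 6
    n_villages: int = 150
    weight_log_mean: float = 5.0  # log-normal census weights
    weight_log_sigma: float = 1.0
    study_start: date = date(2005, 7, 1)
    n_months: int = 49
    clinic_opening_months: tuple[int, ...] = (0, 14, 31, 31)
    # monthly per-capita initiation = init_rate * logistic(a + b * ptt_min)
    init_rate: float = 0.004
    decay_intercept: float = 0.5
    decay_slope: float = -0.02
    bypass_probability: float = 0.2
    transfer_hazard: float = 0.05  # per month, when not at nearest clinic
    background_transfer_rate: float = 0.008  # per month, other reasons
    exit_rate: float = 0.002      # per month, died/lost/stopped
    speeds: SpeedSet = dc_field(default_factory=SpeedSet)
    road_buffer_m: float = 75.0

    def __post_init__(self) -> None:
        for name in ("init_rate", "bypass_probability", "transfer_hazard",
                     "background_transfer_rate", "exit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1], got {v}")
        if not 2 <= len(self.clinic_opening_months) <= 4:
            raise ScenarioError("scenario needs 2-4 clinics")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(origin_x=self.origin_x, origin_y=self.origin_y,
                        cell_size=self.cell_size, n_rows=self.n_rows,
                        n_cols=self.n_cols)

    @property
    def study_end(self) -> date:
        return _add_months(self.study_start, self.n_months) - timedelta(days=1)

    def default_periods(self) -> list[PeriodSpec]:
        """Two comparison periods: second clinic open, then all open."""
        months = sorted(set(self.clinic_opening_months))
        second = _add_months(self.study_start, months[1])
        last = _add_months(self.study_start, months[-1])
        if second == last:  # a single expansion: halve the window after it
            mid = second + (self.study_end - second) / 2
            return [
                PeriodSpec("P1", second, mid),
                PeriodSpec("P2", mid + timedelta(days=1), self.study_end),
            ]
        return [
            PeriodSpec("P1", second, last - timedelta(days=1)),
            PeriodSpec("P2", last, self.study_end),
        ]


@dataclass
class SyntheticDistrict:
    """A generated district plus the ground truth used to plant it."""

    config: ScenarioConfig
    roads: RoadNetwork
    villages: list[Village]
    clinics: list[Clinic]
    records: list[PatientRecord]
    timeline: Timeline
    # ground truth
    patient_truth: list[dict]       # per patient: nearest/bypass at init
    bypass_truth: list[dict]        # per quarter-end: active, bypassing
    table_truth: list[dict]         # per period: a, n1, b, n0

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "roads": outdir / "roads.geojson",
            "villages": outdir / "villages.csv",
            "clinics": outdir / "clinics.csv",
            "register": outdir / "register.csv",
            "truth_patients": outdir / "truth_patients.csv",
            "truth_bypass": outdir / "truth_bypass.csv",
            "truth_tables": outdir / "truth_tables.csv",
        }
        write_roads(self.roads, paths["roads"])
        write_villages(self.villages, paths["villages"])
        write_clinics(self.clinics, paths["clinics"])
        write_register(self.records, paths["register"])
        for key, rows in (("truth_patients", self.patient_truth),
                          ("truth_bypass", self.bypass_truth),
                          ("truth_tables", self.table_truth)):
            with open(paths[key], "w", newline="") as fh:
                if rows:
                    w = csv.DictWriter(fh, fieldnames=list(rows[0]))
                    w.writeheader()
                    w.writerows(rows)
        return paths


def _build_roads(cfg: ScenarioConfig, rng: np.random.Generator) -> RoadNetwork:
    south = cfg.origin_y - cfg.n_rows * cfg.cell_size
    segments = [RoadSegment(
        coords=((cfg.trunk_x, cfg.origin_y - 50.0),
                (cfg.trunk_x, south + 50.0)),
        road_class="tarmac",
    )]
    # feeder tracks run west from the trunk into the hinterland
    ys = np.linspace(cfg.origin_y - 2_000.0, south + 2_000.0,
                     cfg.n_feeder_tracks)
    hi = max(cfg.trunk_x - 1_000.0, 1_000.0)
    lo = min(3_000.0, hi)
    for y in ys:
        length = float(rng.uniform(lo, hi))
        yj = float(y + rng.uniform(-500.0, 500.0))
        segments.append(RoadSegment(
            coords=((cfg.trunk_x, yj), (cfg.trunk_x - length, yj)),
            road_class="track",
        ))
    return RoadNetwork(segments=tuple(segments))


def _place_villages(cfg: ScenarioConfig,
                    rng: np.random.Generator) -> list[Village]:
    south = cfg.origin_y - cfg.n_rows * cfg.cell_size
    east = cfg.origin_x + cfg.n_cols * cfg.cell_size
    villages = []
    for i in range(cfg.n_villages):
        y = float(rng.uniform(south + 300.0, cfg.origin_y - 300.0))
        # most villages hug the trunk road; a minority sit far west
        offset = float(rng.exponential(1_500.0)) + 100.0
        side = -1.0 if rng.random() < 0.8 else 1.0
        x = cfg.trunk_x + side * offset
        x = min(max(x, cfg.origin_x + 300.0), east - 300.0)
        weight = float(rng.lognormal(cfg.weight_log_mean,
                                     cfg.weight_log_sigma))
        villages.append(Village(
            village_id=f"V{i:03d}", name=f"Village {i:03d}",
            x=x, y=y, population_weight=weight,
        ))
    return villages


def _place_clinics(cfg: ScenarioConfig) -> list[Clinic]:
    """Clinics sit on the trunk road, spread north to south; the first
    (district hospital) is central, later ones fill the south then the
    extremes — mirroring a strategic roll-out."""
    south = cfg.origin_y - cfg.n_rows * cfg.cell_size
    span = cfg.origin_y - south
    fractions = (0.45, 0.80, 0.15, 0.62)  # centre, south, north, mid
    names = ("District Hospital", "Southern Rural Hospital",
             "Northern Health Centre", "Central Health Centre")
    clinics = []
    for k, month in enumerate(cfg.clinic_opening_months):
        clinics.append(Clinic(
            clinic_id=f"C{k + 1}", name=names[k],
            x=cfg.trunk_x - 150.0,
            y=cfg.origin_y - fractions[k] * span,
            opening_date=_add_months(cfg.study_start, month),
        ))
    return clinics


def generate(cfg: ScenarioConfig | None = None) -> SyntheticDistrict:
    """Generate the synthetic district, cohort and ground truth."""
    cfg = cfg or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    roads = _build_roads(cfg, rng)
    villages = _place_villages(cfg, rng)
    clinics = _place_clinics(cfg)
    timeline = Timeline(clinics=clinics, study_start=cfg.study_start,
                        study_end=cfg.study_end)

    classes = rasterize_roads(roads, cfg.grid, cfg.road_buffer_m)
    fric = build_friction(classes, cfg.speeds)
    minutes: dict[str, dict[str, float]] = {}
    for c in clinics:
        fld = cumulative_cost(fric, [c])
        tbl = village_travel_times(fld, villages)
        minutes[c.clinic_id] = dict(zip(tbl["village_id"], tbl["minutes"]))

    def nearest_open(vid: str, at: date) -> tuple[str, float]:
        open_ids = sorted(c.clinic_id for c in clinics
                          if c.opening_date <= at)
        best = min(minutes[cid][vid] for cid in open_ids)
        nid = min(cid for cid in open_ids
                  if minutes[cid][vid] <= best + 1e-9)
        return nid, best

    def is_bypass(vid: str, cid: str, at: date) -> bool:
        # bypass means strictly slower than the fastest open clinic, so a
        # tie on travel time still counts as attending the nearest
        _, best = nearest_open(vid, at)
        return minutes[cid][vid] > best + 1e-9

    def longest_standing(at: date) -> str:
        open_ = [c for c in clinics if c.opening_date <= at]
        return min(open_, key=lambda c: (c.opening_date, c.clinic_id)).clinic_id

    # --- cohort simulation, month by month, single RNG stream ---------
    records: list[PatientRecord] = []
    patient_truth: list[dict] = []
    # live bookkeeping: pid -> (village_id, current clinic, active flag)
    state: dict[str, dict] = {}
    pid_counter = 0
    for m in range(cfg.n_months):
        month_start = _add_months(cfg.study_start, m)
        if not timeline.open_clinics(month_start):
            continue
        # initiations per village (draw order: village index ascending)
        for v in villages:
            nid, ptt = nearest_open(v.village_id, month_start)
            decay = 1.0 / (1.0 + math.exp(-(cfg.decay_intercept
                                            + cfg.decay_slope * ptt)))
            lam = v.population_weight * cfg.init_rate * decay
            n_new = int(rng.poisson(lam))
            for _ in range(n_new):
                pid = f"P{pid_counter:05d}"
                pid_counter += 1
                start_day = int(rng.integers(1, 28))
                start = date(month_start.year, month_start.month, start_day)
                if rng.random() < cfg.bypass_probability:
                    chosen = longest_standing(start)
                else:
                    chosen = nid
                text = v.name.upper() if rng.random() < 0.1 else v.name
                rec = PatientRecord(patient_id=pid, village_text=text,
                                    clinic_id=chosen, art_start_date=start,
                                    village_id=v.village_id)
                records.append(rec)
                state[pid] = {"village": v.village_id, "clinic": chosen,
                              "active": True, "rec": rec}
                patient_truth.append({
                    "patient_id": pid, "village_id": v.village_id,
                    "init_clinic": chosen, "nearest_at_init": nid,
                    "bypass_at_init": int(is_bypass(v.village_id, chosen, start)),
                })
        # transfers and exits (draw order: patient id ascending)
        month_end = _add_months(month_start, 1) - timedelta(days=1)
        open_ids = sorted(c.clinic_id for c in clinics
                          if c.opening_date <= month_start)
        for pid in sorted(state):
            st = state[pid]
            if not st["active"] or st["rec"].art_start_date > month_start:
                continue
            nid, _ = nearest_open(st["village"], month_start)
            if st["clinic"] != nid:
                # pull of the nearer clinic once one is available
                p_transfer, dest = cfg.transfer_hazard, nid
            elif len(open_ids) > 1:
                # occasional transfer for non-distance reasons
                p_transfer, dest = cfg.background_transfer_rate, None
            else:
                p_transfer, dest = 0.0, None
            u = rng.random()
            if u < p_transfer:
                if dest is None:
                    others = [cid for cid in open_ids
                              if cid != st["clinic"]]
                    dest = others[int(rng.integers(len(others)))]
                st["rec"].events.append(PatientEvent(
                    event_date=month_end, event_type="transfer_out"))
                st["rec"].events.append(PatientEvent(
                    event_date=month_end, event_type="transfer_in",
                    clinic_id=dest))
                st["clinic"] = dest
            elif u < p_transfer + cfg.exit_rate:
                kind = "died" if rng.random() < 0.5 else "lost"
                st["rec"].events.append(PatientEvent(
                    event_date=month_end, event_type=kind))
                st["active"] = False

    # --- ground truth: bypass proportion at each quarter end ----------
    bypass_truth: list[dict] = []
    for label, _q0, q1 in timeline.quarters():
        if not timeline.open_clinics(q1):
            continue
        n_active = n_bypass = 0
        for rec in records:
            if not rec.active_at(q1):
                continue
            cid = rec.clinic_at(q1)
            nid, _ = nearest_open(rec.village_id, q1)
            n_active += 1
            n_bypass += int(is_bypass(rec.village_id, cid, q1))
        bypass_truth.append({
            "quarter": label, "date": q1.isoformat(),
            "n_active": n_active, "n_bypass": n_bypass,
            "proportion": (n_bypass / n_active) if n_active else 0.0,
        })

    # --- ground truth: 2x2 counts per comparison period ---------------
    table_truth: list[dict] = []
    for period in cfg.default_periods():
        a = n1 = b = n0 = 0
        for rec in records:
            if rec.art_start_date > period.end_date:
                continue
            entry = max(period.start_date, rec.art_start_date)
            if not rec.active_at(entry):
                continue
            cid = rec.clinic_at(entry)
            nid, _ = nearest_open(rec.village_id, entry)
            exposed = is_bypass(rec.village_id, cid, entry)
            transferred = any(
                e.event_type == "transfer_out"
                and period.start_date <= e.event_date <= period.end_date
                for e in rec.events
            )
            if exposed:
                n1 += 1
                a += int(transferred)
            else:
                n0 += 1
                b += int(transferred)
        table_truth.append({"period": period.label, "a": a, "n1": n1,
                            "b": b, "n0": n0})

    return SyntheticDistrict(
        config=cfg, roads=roads, villages=villages, clinics=clinics,
        records=records, timeline=timeline, patient_truth=patient_truth,
        bypass_truth=bypass_truth, table_truth=table_truth,
    )


@dataclass
class PlantedScenario:
    """A minimal two-clinic district carrying exactly specified 2x2
    counts, for exact round-trip checks of the table construction."""

    records: list[PatientRecord]
    villages: list[Village]
    clinics: list[Clinic]
    timeline: Timeline
    periods: list[PeriodSpec]
    roads: RoadNetwork
    grid: GridSpec


def plant_table(tables: list[tuple[str, int, int, int, int]],
                ) -> PlantedScenario:
    """Emit register rows realising exact 2x2 counts per period.

    ``tables`` is a list of ``(label, a, n1, b, n0)``: ``a`` of the
    ``n1`` exposed (not-nearest) patients transfer out during the period,
    ``b`` of the ``n0`` unexposed. All patients live in a single village
    co-located with clinic C1, so attending C2 is the exposure. Each
    period gets a disjoint cohort: patients who do not transfer receive a
    ``stop`` event between periods so counts never bleed across.
    """
    grid = GridSpec(origin_x=0.0, origin_y=1_000.0, cell_size=100.0,
                    n_rows=10, n_cols=30)
    base = date(2000, 1, 1)
    clinics = [
        Clinic(clinic_id="C1", name="Near", x=150.0, y=850.0,
               opening_date=base),
        Clinic(clinic_id="C2", name="Far", x=2_850.0, y=850.0,
               opening_date=base),
    ]
    village = Village(village_id="V1", name="Home", x=150.0, y=850.0,
                      population_weight=100.0)
    # half-year periods with gaps between them, so the stop event that
    # retires a period's cohort falls strictly before the next period
    periods = [
        PeriodSpec(label, date(2001 + i, 1, 1), date(2001 + i, 6, 30))
        for i, (label, *_rest) in enumerate(tables)
    ]
    records: list[PatientRecord] = []
    for period, (label, a, n1, b, n0) in zip(periods, tables):
        if not (0 <= a <= n1 and 0 <= b <= n0):
            raise ScenarioError(f"period {label}: counts exceed margins")
        mid = period.start_date + (period.end_date - period.start_date) // 2
        after = period.end_date + timedelta(days=1)
        k = 0
        for exposed, total, transfers in ((True, n1, a), (False, n0, b)):
            clinic = "C2" if exposed else "C1"
            for j in range(total):
                pid = f"{label}-{'E' if exposed else 'U'}{j:04d}"
                events = []
                if j < transfers:
                    events.append(PatientEvent(event_date=mid,
                                               event_type="transfer_out"))
                else:
                    events.append(PatientEvent(event_date=after,
                                               event_type="stop"))
                records.append(PatientRecord(
                    patient_id=pid, village_text=village.name,
                    clinic_id=clinic, art_start_date=period.start_date,
                    events=events, village_id=village.village_id,
                ))
                k += 1
    roads = RoadNetwork(segments=(RoadSegment(
        coords=((0.0, 850.0), (3_000.0, 850.0)), road_class="track"),))
    timeline = Timeline(clinics=clinics, study_start=base,
                        study_end=periods[-1].end_date)
    return PlantedScenario(records=records, villages=[village],
                           clinics=clinics, timeline=timeline,
                           periods=periods, roads=roads, grid=grid)
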