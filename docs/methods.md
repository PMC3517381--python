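# Methods

## The cost-surface travel-time model

Travel time is modelled on a regular projected grid (default 100 m
cells, row 0 northernmost). Each cell belongs to one of three surface
classes, assigned from the vector road network: a cell is *tarmac* if
its centre lies within the buffer distance (default 75 m) of a tarmac
polyline, else *track* if within the buffer of a track, else *other*.
Cell membership is decided by the cell centre, not by area overlap: the
rule is deterministic and is verified against a brute-force
point-to-segment distance computation in the tests. Tarmac takes
precedence over track on overlapping corridors — a traveller in a mixed
cell uses the faster surface. Distances to polylines are exact
(shapely), so buffering is monotone: enlarging the buffer never
declassifies a road cell.

Each class carries an assumed speed, converted once to a friction value
of `60/(1000·v)` minutes per metre:

| class  | default speed | rationale |
|--------|---------------|-----------|
| tarmac | 35 km/h       | minibus along the main road, net of stops and checkpoints |
| track  | 5 km/h        | bicycle taxi / occasional motorised lift on passable tracks |
| other  | 3.5 km/h      | straight-line-equivalent walking speed over open terrain |

The cumulative travel-time field from a set of clinics is the
multi-source shortest path over the 8-connected cell graph with edge
cost `d_ij·(t_i+t_j)/2` (`d_ij` = cell size, or cell size·√2 on
diagonals) — the standard GIS cost-distance formulation. The solve is
delegated to `scipy.sparse.csgraph.dijkstra`; the graph construction and
cost model are this package's own, and the tests compare the complete
field against an independently constructed `networkx` oracle on random
friction surfaces (tolerance 1e-9). 16-connectivity is not implemented;
the 8-neighbour graph overestimates times for directions between the 8
compass bearings by at most ~8%, uniformly, which cancels in the
potential-vs-actual comparisons the package exists for.

Least-cost paths are recovered by steepest-descent backtracking over
predecessors satisfying `T(i) = T(j) + cost(i,j)` within 1e-9 relative
slack, ties broken in the fixed order N, NE, E, SE, S, SW, W, NW for
determinism. Path length is the sum of `d_ij` along the route (a route
distance, not a straight line). Clinics and query points snap to the
nearest cell centre; snapping displacement is below cell_size·√2/2 and
is logged.

Excluded by design: seasonality and river crossings, altitude, one-way
or scheduled transport, and anisotropic costs. Inputs must be projected
metres; coordinates that look like lon/lat are rejected unless
explicitly overridden, because the engine does no geodesy.

## Monitoring metrics

At a snapshot date, with open-clinic set *S*:

- **PTT** (potential travel time) of a village: `min_{c∈S} T(v, c)`.
  The cell graph is undirected, so the field computed *from* each clinic
  gives village→clinic times for all villages in one solve per clinic;
  these per-clinic fields are cached across snapshot dates.
- **ATT** (actual travel time) of a patient: time to the clinic
  attended at that date (last transfer-in on/before the date, else the
  starting clinic). ATT ≥ PTT by construction.
- **attends_nearest**: the attended clinic achieves the minimum travel
  time within a 1e-9 tolerance; nearest-clinic identity ties break to
  the lowest clinic id. The bypass proportion is the fraction of active
  patients with attends_nearest false; it is identically 0 with one open
  clinic.

Population summaries weight villages by census size; patient summaries
are unweighted (each patient once). The weighted quantile is the
smallest value whose cumulative normalised weight reaches q, verified
against a repeat-expansion oracle for integer weights. Median confidence
intervals use the percentile bootstrap (default B = 1000, seeded);
population medians resample villages with probability proportional to
weight. Simulation puts the percentile interval's coverage for a
continuous median near its nominal 95% (the test requires ≥ 93%).
Quarterly snapshots are taken at calendar-quarter ends; times are kept
unrounded internally and rounded to 0.1 min only in output tables.

## Register handling

Registers are long-format CSV: one `start` row per patient plus event
rows (`transfer_out`, `transfer_in`, `died`, `lost`, `stop`). An
in-district move is a same-day `transfer_out`/`transfer_in` pair and
keeps the patient in follow-up at the new clinic; a `transfer_out` with
no subsequent `transfer_in` ends follow-up, as do the terminal events. A
patient is active at a date if they started on/before it and follow-up
did not end strictly before it. Quarterly start counts exclude patients
who arrived from outside (a `transfer_in` not preceded by an in-register
`transfer_out`); transfers out are attributed to the clinic being left.

Free-text villages link to the gazetteer by normalised exact match
(case-fold, trim, collapse whitespace) and then a curated alias table.
Fuzzy matching is deliberately not implemented — it is unauditable —
and unmatched records are excluded from travel-time analyses but
counted in every report header.

## Bypass → transfer inference

Per period, exposure is *not attending the nearest open clinic* at
period entry (period start, or ART start if later) and the outcome is a
transfer-out dated within the period. The risk ratio is the crude ratio
of risks, which is the log-binomial maximum-likelihood estimate for a
single binary exposure; its CI is the Katz log-scale Wald interval.
The period-interaction test compares the saturated log-link binomial
model (one risk per cell) with the main-effects model
`log p = b0 + b_period + b_exposure`, fitted by SLSQP maximisation of
the binomial log-likelihood from a deterministic start (log crude risks)
under the constraint `log p ≤ 0` per cell, tolerance 1e-12; the
statistic is referred to χ²(1). A closed-form Wald contrast of the two
log risk ratios is always computed alongside as a convergence-free
cross-check; on well-behaved tables the two agree to ~1e-3 in p.
Zero event cells flag the CI as undefined rather than inventing a
continuity correction.

## The synthetic district

The generator emulates the *shape* of a lakeshore district and a staged
roll-out, so that every pipeline stage has known ground truth:

- geometry: a 12 × 30 km grid, one north-south tarmac trunk road,
  6 feeder tracks, 150 villages placed with an exponential offset from
  the trunk (80% west), log-normal census weights (μ=5, σ=1 on the log
  scale, median ≈ 148);
- roll-out: four clinics on the trunk road opening at months 0, 14, 31
  and 31 of a 49-month window, central hospital first;
- cohort: monthly initiations per village are Poisson with per-capita
  rate `0.004 · logistic(0.5 − 0.02·PTT_minutes)` — initiation decays
  with travel time; new patients choose their nearest open clinic except
  with probability 0.2 they choose the longest-standing clinic (the
  district-hospital pull); patients not at their nearest open clinic
  transfer to it with hazard 0.05/month; any patient at their nearest
  clinic moves elsewhere with probability 0.008/month (non-distance
  reasons) when more than one clinic is open; exits (died/lost) occur at
  0.002/month.

All draws come from one seeded NumPy generator in documented order, so a
fixed seed reproduces every output file byte for byte. The ground truth
written alongside the fixtures (per-patient bypass at initiation,
per-quarter bypass proportions, per-period 2×2 counts) is computed from
the generator's own bookkeeping with the same time-based bypass rule the
monitor uses, so recovery checks are exact, not statistical.

What the generator does **not** emulate: real demography or HIV
epidemiology, misreported residence, seasonal road closures, or the
within-village dispersion of households. Passing the recovery tests
therefore demonstrates the pipeline's internal correctness under the
model's assumptions — not the accuracy of the travel-time model for any
real district, which depends on the assumed speeds (hence the
sensitivity sweep) and on village-centroid positional error.

`plant_table` is the deterministic counterpart for the inference stage:
it emits register rows realising exact 2×2 counts in a minimal
two-clinic district (everyone lives beside clinic C1; attending C2 is
the exposure), with period cohorts kept disjoint by retiring
non-transferred patients between periods.

## Problem sizes and defaults

The default synthetic district (36 000 cells, ~3 700 patients,
17 quarters) runs the full monitoring series in a few seconds; the
sensitivity sweep uses the 8-corner design (each speed range at its
endpoints) because the sweep's purpose is to bound the trend direction,
and corners bound the range at minimal cost — a full factorial at any
level count is available. Bootstrap replicates default to B = 1000
(B/10 within the sensitivity sweep, where only trend signs are read).

## Known limitations

- One travel-time surface per speed set; no time-varying network.
- The snapped clinic cell may fall just off the road corridor for
  clinics digitised away from the centreline; times to such clinics
  include a short walking approach, which is usually realistic but is
  not configurable.
- The interaction LRT's constrained fit can in principle sit on the
  `p = 1` boundary for extreme tables; the Wald contrast is reported
  precisely so such cases remain interpretable.
- Villages are points; within-village travel heterogeneity is ignored.
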