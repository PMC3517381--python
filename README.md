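# accessmon

Monitoring how the decentralisation of chronic-care services changes
patient travel time.

When a health programme opens new clinics in a rural district — the
motivating case is antiretroviral-therapy (ART) roll-out in sub-Saharan
Africa — planners want to know three things: how much closer care has
become for the general population, how much closer it has become for the
patients actually in care, and whether patients in fact use the nearest
clinic. `accessmon` answers all three from routinely collected data: a
classed road network, village coordinates with census population weights,
clinic locations with opening dates, and the patient register.

## Method

**Travel-time engine.** The district is discretised onto a 100 m grid.
Each cell is classed *tarmac*, *track* or *other* by buffering the road
network (75 m each side; tarmac wins on overlap) and carries a traversal
cost of `60/(1000·v)` minutes per metre, with default speeds
`v = 35 / 5 / 3.5` km/h for the three classes. Travel time from the
clinics is the multi-source shortest path over the 8-connected cell
graph with the standard cost-distance edge weight
`d_ij · (t_i + t_j)/2`, where `d_ij` is the centre-to-centre distance.

**Monitoring metrics.** For a snapshot date with open-clinic set *S*:

- *Potential travel time* (PTT) of a village is
  `min_{c ∈ S} T(village, c)` — travel time if everyone used the nearest
  open clinic;
- *Actual travel time* (ATT) of a patient is `T(village, attended
  clinic)`, so ATT ≥ PTT by construction;
- a patient *bypasses* when their ATT exceeds their PTT (beyond a 1e-9
  tie tolerance).

Population summaries weight villages by census size; patient summaries
count each patient once. Medians carry 95% percentile-bootstrap
confidence intervals. The series is recomputed at every calendar-quarter
end as clinics open.

**Bypass → transfer inference.** For each comparison period, patients are
cross-classified by exposure (not attending the nearest open clinic at
period entry) and outcome (transfer-out during the period). The risk
ratio is the log-binomial MLE `(a/n1)/(b/n0)` with the Katz log-scale
interval `exp(ln RR ± z·√(1/a − 1/n1 + 1/b − 1/n0))`, and the change in
association between periods is tested with a 1-df likelihood-ratio test
of the period × exposure interaction under the log-link binomial model
(a Wald contrast of the two log risk ratios is reported alongside).

**Synthetic district.** Because patient registers are confidential, the
package ships a seeded generator that emulates a lakeshore-like district:
a tarmac trunk road with feeder tracks, ~150 villages with log-normal
census weights, four clinics opening sequentially, and a cohort whose
initiation follows a logistic distance-decay in PTT and whose clinic
choice mixes nearest-clinic attendance with initiation-clinic
stickiness. Every analysis stage can therefore be verified against known
ground truth.

## Worked example

```bash
accessmon synth --out district/
accessmon run --roads district/roads.geojson --villages district/villages.csv \
    --clinics district/clinics.csv --register district/register.csv \
    --period P1:2006-09-01:2008-01-31 --period P2:2008-02-01:2009-07-31 \
    --seed 1 --out report/
```

`report/timeseries.csv` then holds one row per quarter. On the default
synthetic district the series runs (values printed by the pipeline):

```
quarter  n_patients  bypass_proportion  pop_ptt_median  ptt_median  att_median
 2005Q3         200              0.000            33.8        28.6        28.6
 2006Q3        1039              0.358            28.1        27.2        30.5
 2008Q1        2364              0.550            22.0        19.8        27.5
 2009Q3        3554              0.248            22.0        19.8        24.6
```

Read: with one clinic open everyone attends their nearest clinic and the
population's median potential travel time is 33.8 min; each opening
lowers PTT (33.8 → 28.1 → 22.0 min); bypass spikes when an opening
changes who is nearest (0.358, 0.550) and then decays as patients
transfer; actual travel time stays above potential as long as anyone
bypasses. `report/table1.csv` gives the period risk ratios and the
interaction-test p-value, and `report/sensitivity.csv` repeats the series
under the eight corner combinations of the speed ranges
(walking 3–6, track 5–8, tarmac 30–45 km/h).

As a statistics check, feeding the published study's printed counts
through the same routines:

```python
>>> from accessmon import TwoByTwoTable, risk_ratio, interaction_lrt
>>> t1 = TwoByTwoTable("Sep06-Jan08", a=121, n1=186, b=418, n0=1998)
>>> t2 = TwoByTwoTable("Feb08-Aug09", a=145, n1=610, b=370, n0=3577)
>>> round(risk_ratio(t1).rr, 2), round(risk_ratio(t2).rr, 2)
(3.11, 2.3)
>>> round(interaction_lrt([t1, t2]).p_value, 3)
0.007
```

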