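"""Risk-ratio inference for bypass vs transfer-out.

Each study period yields a 2x2 table: exposure is *not attending the
nearest open clinic* at the period start (or at ART start if later),
outcome is a transfer-out during the period. The risk ratio is the
log-binomial maximum-likelihood estimate, which for a single binary
exposure is the crude ratio of risks

    rr = (a / n1) / (b / n0),

with the Katz log-scale Wald interval

    exp( ln rr  ±  z * sqrt(1/a - 1/n1 + 1/b - 1/n0) ).

Whether the association differs between periods is tested with a
likelihood-ratio test: the saturated log-link binomial model (period x
exposure interaction) against the main-effects model fitted by
constrained maximum likelihood (all fitted risks <= 1), on 1 degree of
freedom. A closed-form Wald contrast of the two log risk ratios is always
reported alongside as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .monitor import AccessSnapshot
from .registry import PatientRecord, PeriodSpec


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class TwoByTwoTable:
    """Transfer outcome by nearest-clinic attendance for one period.

    ``a`` transfers among ``n1`` patients not at their nearest clinic
    (exposed); ``b`` transfers among ``n0`` patients at their nearest
    clinic (unexposed).
    """

    period_label: str
    a: int
    n1: int
    b: int
    n0: int

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("n1", self.n1), ("b", self.b),
                        ("n0", self.n0)):
            if int(v) != v or v < 0:
                raise InferenceError(f"{name} must be a nonnegative integer")
        if self.a > self.n1 or self.b > self.n0:
            raise InferenceError("cell count exceeds its margin")

    @property
    def risk_exposed(self) -> float:
        return self.a / self.n1

    @property
    def risk_unexposed(self) -> float:
        return self.b / self.n0


@dataclass(frozen=True)
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    level: float
    se_log_rr: float | None = None
    ci_defined: bool = True


def risk_ratio(table: TwoByTwoTable, level: float = 0.95) -> RiskRatioResult:
    """Risk ratio with the Katz log (Wald) confidence interval.

    With a zero cell the point estimate is still returned when defined,
    but the CI is flagged unavailable.
    """
    if table.n1 == 0 or table.n0 == 0:
        raise InferenceError("both exposure groups must be non-empty")
    if table.b == 0:
        raise InferenceError("risk ratio undefined: no events in the "
                             "unexposed group")
    rr = table.risk_exposed / table.risk_unexposed
    if table.a == 0:
        return RiskRatioResult(rr=rr, ci_low=math.nan, ci_high=math.nan,
                               level=level, ci_defined=False)
    se = math.sqrt(1 / table.a - 1 / table.n1 + 1 / table.b - 1 / table.n0)
    z = stats.norm.ppf(0.5 + level / 2)
    log_rr = math.log(rr)
    return RiskRatioResult(
        rr=rr,
        ci_low=math.exp(log_rr - z * se),
        ci_high=math.exp(log_rr + z * se),
        level=level,
        se_log_rr=se,
    )


def _binom_ll(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial log-likelihood without the combinatorial constant."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (n - y) * np.log(1 - p)))


@dataclass(frozen=True)
class InteractionLRT:
    statistic: float
    df: int
    p_value: float
    converged: bool
    wald_z: float
    wald_p: float


def interaction_lrt(tables: list[TwoByTwoTable]) -> InteractionLRT:
    """Likelihood-ratio test for a period-by-exposure interaction.

    Compares the saturated log-link binomial model (one risk per cell)
    against the main-effects model ``log p = b0 + b_period + b_exposure``
    fitted by maximum likelihood under the constraint that all fitted
    risks stay below 1. The statistic is referred to chi-square(1). A
    Wald contrast of the two log risk ratios (Katz standard errors) is
    returned alongside.
    """
    if len(tables) != 2:
        raise InferenceError("interaction test needs exactly 2 tables")
    for t in tables:
        if min(t.a, t.b, t.n1 - t.a, t.n0 - t.b) < 0 or t.n1 == 0 or t.n0 == 0:
            raise InferenceError(f"table {t.period_label}: invalid margins")
    y = np.array([t.b for t in tables] + [t.a for t in tables], dtype=float)
    n = np.array([t.n0 for t in tables] + [t.n1 for t in tables], dtype=float)
    period = np.array([0.0, 1.0, 0.0, 1.0])
    exposed = np.array([0.0, 0.0, 1.0, 1.0])
    X = np.column_stack([np.ones(4), period, exposed])

    ll_sat = _binom_ll(y, n, y / n)

    def neg_ll(beta: np.ndarray) -> float:
        return -_binom_ll(y, n, np.exp(X @ beta))

    # start at log crude risks: baseline risk and pooled effects
    p0 = max(tables[0].risk_unexposed, 1e-6)
    rr_pool = ((tables[0].a + tables[1].a) / (tables[0].n1 + tables[1].n1)) / \
              max((tables[0].b + tables[1].b) / (tables[0].n0 + tables[1].n0),
                  1e-6)
    x0 = np.array([math.log(p0), 0.0, math.log(max(rr_pool, 1e-6))])
    cons = [{"type": "ineq",
             "fun": lambda beta, row=X[i]: -float(row @ beta) - 1e-9}
            for i in range(4)]  # log p_i <= 0 for every cell
    res = optimize.minimize(neg_ll, x0, method="SLSQP", constraints=cons,
                            options={"ftol": 1e-12, "maxiter": 500})
    ll_main = -float(res.fun)
    statistic = max(0.0, 2.0 * (ll_sat - ll_main))
    p_value = float(stats.chi2.sf(statistic, df=1))

    rr1 = risk_ratio(tables[0])
    rr2 = risk_ratio(tables[1])
    se = math.sqrt(rr1.se_log_rr ** 2 + rr2.se_log_rr ** 2)
    wald_z = (math.log(rr1.rr) - math.log(rr2.rr)) / se
    wald_p = float(2 * stats.norm.sf(abs(wald_z)))
    return InteractionLRT(statistic=statistic, df=1, p_value=p_value,
                          converged=bool(res.success), wald_z=wald_z,
                          wald_p=wald_p)


def build_tables(snapshots: dict[str, AccessSnapshot],
                 records: list[PatientRecord],
                 periods: list[PeriodSpec]) -> list[TwoByTwoTable]:
    """Build one 2x2 table per period from access snapshots.

    ``snapshots`` maps period label to a period-entry snapshot (see
    ``monitor.period_entry_snapshot``): one row per patient evaluated at
    the period start, or at ART start if later. Exposure is *not*
    attending the nearest open clinic at that entry point; the outcome is
    a transfer-out event dated within the period.
    """
    for i, p in enumerate(periods):
        for q in periods[i + 1:]:
            if p.start_date <= q.end_date and q.start_date <= p.end_date:
                raise InferenceError(
                    f"periods {p.label} and {q.label} overlap"
                )
    tables = []
    for period in periods:
        snap = snapshots[period.label]
        exposure = dict(zip(snap.patients["patient_id"],
                            ~snap.patients["attends_nearest"]))
        a = n1 = b = n0 = 0
        for rec in records:
            if rec.patient_id not in exposure:
                continue
            exposed = bool(exposure[rec.patient_id])
            transferred = any(
                e.event_type == "transfer_out"
                and period.start_date <= e.event_date <= period.end_date
                for e in rec.events
            )
            if exposed:
                n1 += 1
                a += transferred
            else:
                n0 += 1
                b += transferred
        tables.append(TwoByTwoTable(period_label=period.label, a=a, n1=n1,
                                    b=b, n0=n0))
    return tables


def table1_frame(tables: list[TwoByTwoTable],
                 level: float = 0.95) -> pd.DataFrame:
    """Summary table mirroring the published layout: per period, the
    transfer percentage in each exposure group and the risk ratio with
    its CI."""
    rows = []
    for t in tables:
        try:
            res = risk_ratio(t, level=level)
            rr, lo, hi = (round(res.rr, 2), round(res.ci_low, 2),
                          round(res.ci_high, 2))
        except InferenceError:  # empty group or no unexposed events
            rr = lo = hi = np.nan
        rows.append({
            "period": t.period_label,
            "group": "not_nearest",
            "transferred_pct": (round(100 * t.risk_exposed, 1)
                                if t.n1 else np.nan),
            "n": t.a, "N": t.n1,
            "rr": rr, "ci_low": lo, "ci_high": hi,
        })
        rows.append({
            "period": t.period_label,
            "group": "nearest",
            "transferred_pct": (round(100 * t.risk_unexposed, 1)
                                if t.n0 else np.nan),
            "n": t.b, "N": t.n0,
            "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        })
    return pd.DataFrame(rows)
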