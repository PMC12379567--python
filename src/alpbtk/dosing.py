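"""Dietary input functions and SCIT dose schedules with zero-order depots.

Two exposure routes feed the model:

* continuous dietary intake, tiered by age in mg Al/kg body weight/week
  (infant tiers 0.1/0.2/0.4 for months 0-3/4-6/7-9, then 0.8 from 10 months
  on), of which a fraction ``F_oral`` = 0.17% reaches plasma;
* subcutaneous injections of adjuvant-bound Al, each forming a depot that
  releases at a zero-order rate ``k * dose`` (fraction of the administered
  dose per day) until exhaustion at ``1/k`` days, with 100% of the released
  amount entering plasma.

The adjuvant release rates are 0.0024864/day for commercial aluminium
hydroxide (Ahy, depot lifetime ~402 days) and 0.0082392/day for in-situ
precipitated hydroxide (Ains, ~121 days); both vary lognormally between
individuals with a 50% coefficient of variation.

Maintenance schedules use a 28-day interval; a treatment-year is 13 doses
(13 x 28 = 364 days), so 5/10/40 treatment-years give 65/130/520 doses.
Updosing phases carry negligible Al and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physiology import DAYS_PER_YEAR, PhysiologyProfile, body_weight

DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0
TREATMENT_YEAR_D = 364.0
DOSES_PER_TREATMENT_YEAR = 13

#: Zero-order depot release rates, fraction of administered dose per day.
K_RELEASE = {"Ahy": 0.0024864, "Ains": 0.0082392}

#: Tolerable weekly intake for Al, mg/kg body weight/week.
TWI_MG_KG_WK = 1.0

DEFAULT_ORAL_F = 0.0017


@dataclass(frozen=True)
class AdjuvantKinetics:
    """Depot release rates per adjuvant type and their population variability."""

    k_release: dict = field(default_factory=lambda: dict(K_RELEASE))
    iiv_cv: float = 0.50

    def __post_init__(self):
        if any(k <= 0 for k in self.k_release.values()):
            raise ValueError("release rates must be positive")


@dataclass(frozen=True)
class DietaryScheme:
    """Age-tiered dietary Al intake plus oral bioavailability.

    ``tiers`` are (age_lo_months, age_hi_months, mg Al/kg/week) and must
    partition [0, inf); the last tier is open-ended (hi = inf).
    """

    tiers: tuple = (
        (0.0, 3.0, 0.1),
        (3.0, 6.0, 0.2),
        (6.0, 9.0, 0.4),
        (9.0, 12.0, 0.8),
        (12.0, np.inf, 0.8),
    )
    oral_bioavailability: float = DEFAULT_ORAL_F

    def __post_init__(self):
        if not 0.0 < self.oral_bioavailability < 1.0:
            raise ValueError("oral bioavailability must be a fraction in (0, 1)")
        lo = 0.0
        for a, b, x in self.tiers:
            if a != lo or b <= a or x <= 0:
                raise ValueError("tiers must partition [0, inf) with positive intakes")
            lo = b
        if not np.isinf(lo):
            raise ValueError("last tier must be open-ended")

    def intake_mg_kg_wk(self, age_y: float) -> float:
        """Tier intake (mg Al/kg/week) at an age in years."""
        months = age_y * 12.0
        for a, b, x in self.tiers:
            if a <= months < b:
                return x
        raise ValueError("age outside tier partition")

    def tier_boundaries_days(self) -> list:
        """Ages (days) at which the intake tier changes."""
        return [b * DAYS_PER_MONTH for _, b, _ in self.tiers[:-1]]


def dietary_ingestion_rate(scheme: DietaryScheme, profile: PhysiologyProfile, age_y) -> float:
    """Ingested Al (ug/day): tier [mg/kg/wk] x body weight [kg] x 1000 / 7."""
    age_y = float(age_y)
    return scheme.intake_mg_kg_wk(age_y) * float(body_weight(profile, age_y)) * 1000.0 / 7.0


def dietary_systemic_rate(
    scheme: DietaryScheme, profile: PhysiologyProfile, age_y, oral_f_mult: float = 1.0
) -> float:
    """Systemic dietary input (ug/day) = ingestion x F_oral x individual multiplier."""
    return (
        dietary_ingestion_rate(scheme, profile, age_y)
        * scheme.oral_bioavailability
        * oral_f_mult
    )


@dataclass(frozen=True)
class DoseEvent:
    """One s.c. injection: time since birth (days), Al amount (mg), adjuvant type."""

    time: float
    amount: float
    adjuvant: str = "Ahy"

    def __post_init__(self):
        if self.time < 0 or self.amount <= 0:
            raise ValueError("dose events need time >= 0 and amount > 0")
        if self.adjuvant not in K_RELEASE:
            raise ValueError(f"unknown adjuvant {self.adjuvant!r}")


@dataclass(frozen=True)
class ScitSchedule:
    """A perennial full-dose maintenance treatment block."""

    start_age_y: float
    treatment_years: int
    interval_days: float = 28.0
    dose_mg: float = 1.25
    adjuvant: str = "Ahy"
    n_parallel: int = 1

    def __post_init__(self):
        if self.interval_days <= 0 or self.dose_mg <= 0:
            raise ValueError("interval and dose must be positive")
        if self.treatment_years < 1 or self.n_parallel < 1:
            raise ValueError("treatment_years and n_parallel must be >= 1")

    @property
    def n_doses(self) -> int:
        return DOSES_PER_TREATMENT_YEAR * self.treatment_years * self.n_parallel

    @property
    def end_day(self) -> float:
        """Day the last treatment-year ends (start + years x 364 d)."""
        return self.start_age_y * DAYS_PER_YEAR + self.treatment_years * TREATMENT_YEAR_D


def build_scit_schedule(spec: ScitSchedule) -> list:
    """Expand a schedule into dose events at start + k x interval, k = 0..13*years-1."""
    start = spec.start_age_y * DAYS_PER_YEAR
    n = DOSES_PER_TREATMENT_YEAR * spec.treatment_years
    events = []
    for k in range(n):
        t = start + k * spec.interval_days
        for _ in range(spec.n_parallel):
            events.append(DoseEvent(time=t, amount=spec.dose_mg, adjuvant=spec.adjuvant))
    return events


def cumulative_dose(events) -> float:
    """Total administered Al (mg) over a list of dose events."""
    return float(sum(e.amount for e in events))


def depot_release(events, k_ind: float, t) -> np.ndarray:
    """Total depot release rate (ug/day) at time(s) t for one individual.

    Each depot releases ``k_ind * amount`` (converted to ug) from its dose
    time until exhaustion ``1/k_ind`` days later, so the cumulative release
    per depot equals exactly the administered amount.
    """
    if k_ind <= 0:
        raise ValueError("k_ind must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    dur = 1.0 / k_ind
    for e in events:
        active = (t >= e.time) & (t < e.time + dur)
        out = out + active * (k_ind * e.amount * 1000.0)
    return out


def release_breakpoints(events, k_ind: float):
    """Piecewise-constant depot release: (breakpoints, rate per interval).

    Returns times (days, sorted, unique) and the release rate (ug/day) on
    each interval [times[i], times[i+1]); the rate after the last breakpoint
    is zero.
    """
    if k_ind <= 0:
        raise ValueError("k_ind must be positive")
    dur = 1.0 / k_ind
    deltas = {}
    for e in events:
        r = k_ind * e.amount * 1000.0
        deltas[e.time] = deltas.get(e.time, 0.0) + r
        deltas[e.time + dur] = deltas.get(e.time + dur, 0.0) - r
    times = np.array(sorted(deltas), dtype=float)
    rates = np.cumsum([deltas[t] for t in times])
    rates = np.where(np.abs(rates) < 1e-9, 0.0, rates)  # kill rounding residue
    return times, rates


def released_by(events, k_ind: float, t_end: float) -> float:
    """Exact cumulative amount (ug) released from all depots by time t_end."""
    dur = 1.0 / k_ind
    tot = 0.0
    for e in events:
        tot += e.amount * 1000.0 * min(max(t_end - e.time, 0.0), dur) / dur
    return tot


def schedule_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": [e.time for e in events],
            "amount_mg": [e.amount for e in events],
            "adjuvant": [e.adjuvant for e in events],
        }
    )


def schedule_from_frame(df: pd.DataFrame) -> list:
    return [
        DoseEvent(float(r.time_days), float(r.amount_mg), str(r.adjuvant))
        for r in df.itertuples()
    ]
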