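"""Costing, QALY accrual and incremental cost-effectiveness comparison.

All monetary amounts are 2013 US dollars, as billed in the Chinese
healthcare system.  Chemotherapy doses are scaled by body surface area
(Mosteller formula); intravenous drugs are billed per opened vial
(unused remainder discarded), oral drugs per dispensed tablet/capsule
band.  Recurrence care is a mix of salvage chemotherapy (86.5% of
patients, a median of seven 3-week cycles) and supportive care (13.5%),
with supportive care continuing for everyone after the salvage phase.
A one-time palliative end-of-life cost is charged per cancer death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import WEEKS_PER_YEAR, CohortTrace, EconSettings
from .survival import HazardRatio

__all__ = [
    "PatientProfile",
    "CostItem",
    "CostTable",
    "UtilitySet",
    "DrugComponent",
    "Regimen",
    "RecurrenceCare",
    "StrategySpec",
    "CEResult",
    "compute_bsa",
    "units_required",
    "adjuvant_cost_stream",
    "recurrence_cost_profile",
    "accrue",
    "icer_frontier",
    "net_health_benefit",
    "net_monetary_benefit",
    "default_cost_table",
]


# ---------------------------------------------------------------------------
# patient profile and dosing


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for body-surface-area dosing."""

    weight_kg: float = 65.0
    height_m: float = 1.64

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_m <= 0:
            raise ValueError("weight and height must be positive")

    @property
    def bsa(self) -> float:
        return compute_bsa(self)


def compute_bsa(profile: PatientProfile) -> float:
    """Body surface area (m^2) by the Mosteller formula, 2 decimals."""
    raw = math.sqrt(profile.weight_kg * profile.height_m * 100.0 / 3600.0)
    return round(raw, 2)


def units_required(dose_mg: float, unit_size_mg: float, rounding: str = "up") -> int:
    """Billable units for a dose.

    ``rounding="up"`` bills every opened unit (vial-discard rule);
    ``rounding="nearest"`` rounds the dose to the nearest whole unit, as
    dispensed in clinical dose banding for oral agents (ties round up).
    """
    if dose_mg < 0:
        raise ValueError("dose must be nonnegative")
    if unit_size_mg <= 0:
        raise ValueError("unit size must be positive")
    ratio = dose_mg / unit_size_mg
    if rounding == "up":
        return int(math.ceil(ratio - 1e-9))
    if rounding == "nearest":
        return int(math.floor(ratio + 0.5))
    raise ValueError(f"unknown rounding mode: {rounding!r}")


# ---------------------------------------------------------------------------
# costs and utilities


@dataclass(frozen=True)
class CostItem:
    """Unit cost with its plausible range (median, low, high)."""

    median: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.median <= self.high):
            raise ValueError(
                f"require 0 <= low <= median <= high, got "
                f"({self.low}, {self.median}, {self.high})"
            )

    @classmethod
    def fixed(cls, value: float) -> "CostItem":
        return cls(value, value, value)


@dataclass(frozen=True)
class CostTable:
    """Unit costs of the model (2013 USD)."""

    capecitabine_per_500mg: CostItem = CostItem.fixed(6.6)
    s1_per_20mg: CostItem = CostItem(9.6, 7.9, 10.1)
    oxaliplatin_per_50mg: CostItem = CostItem(88.9, 77.3, 464.5)
    followup_per_unit: CostItem = CostItem(56.5, 42.3, 70.6)
    tests_s1_per_6wk: CostItem = CostItem(197.8, 15.9, 317.5)
    salvage_per_3wk: CostItem = CostItem(2334.6, 1429.3, 3323.2)
    end_of_life: CostItem = CostItem(1460.3, 1055.3, 2085.7)
    supportive_per_cycle: CostItem = CostItem(115.2, 31.7, 317.5)
    adr_s1_per_6wk: CostItem = CostItem(42.3, 7.9, 79.4)
    adr_xelox_per_3wk: CostItem = CostItem(68.9, 15.9, 158.7)
    hosp_xelox_per_3wk: CostItem = CostItem(373.0, 238.1, 793.7)

    def get(self, key: str) -> CostItem:
        try:
            return getattr(self, key)
        except AttributeError:
            raise KeyError(f"unknown cost item: {key!r}") from None

    def with_value(self, key: str, value: float) -> "CostTable":
        """Copy with one item's median replaced (range left untouched)."""
        item = self.get(key)
        return replace(self, **{key: CostItem(value, min(item.low, value), max(item.high, value))})

    def keys(self) -> list[str]:
        import dataclasses

        return [f.name for f in dataclasses.fields(self)]


def default_cost_table() -> CostTable:
    return CostTable()


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (time trade-off valuations)."""

    u_rfs: float = 0.88
    u_rec: float = 0.42
    u_rfs_range: tuple[float, float] = (0.80, 0.97)
    u_rec_range: tuple[float, float] = (0.28, 0.63)

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_rec <= self.u_rfs <= 1.0):
            raise ValueError("require 0 <= u_rec <= u_rfs <= 1")


# ---------------------------------------------------------------------------
# strategies


@dataclass(frozen=True)
class DrugComponent:
    """One drug of an adjuvant regimen.

    ``administrations_per_cycle`` counts separately billed doses in one
    treatment cycle (e.g. twice daily for 28 days = 56).
    """

    name: str
    dose_mg_per_m2: float
    unit_size_mg: float
    cost_key: str
    administrations_per_cycle: int
    rounding: str = "up"

    def units_per_administration(self, bsa: float) -> int:
        return units_required(self.dose_mg_per_m2 * bsa, self.unit_size_mg, self.rounding)

    def cost_per_cycle(self, bsa: float, costs: CostTable) -> float:
        unit_cost = costs.get(self.cost_key).median
        return (
            self.units_per_administration(bsa)
            * unit_cost
            * self.administrations_per_cycle
        )


@dataclass(frozen=True)
class Regimen:
    """Adjuvant chemotherapy schedule."""

    cycle_length_weeks: int
    n_cycles: int
    drugs: tuple[DrugComponent, ...]
    percycle_cost_keys: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cycle_length_weeks <= 0 or self.n_cycles <= 0:
            raise ValueError("cycle length and count must be positive")

    @property
    def duration_weeks(self) -> int:
        return self.cycle_length_weeks * self.n_cycles


@dataclass(frozen=True)
class RecurrenceCare:
    """Care mix after relapse."""

    salvage_fraction: float = 0.865
    supportive_fraction: float = 0.135
    salvage_cycles: int = 7
    salvage_cycle_weeks: int = 3
    supportive_cycle_weeks: int = 3

    def __post_init__(self) -> None:
        if abs(self.salvage_fraction + self.supportive_fraction - 1.0) > 1e-9:
            raise ValueError("care-mix fractions must sum to 1")
        if self.salvage_cycles <= 0:
            raise ValueError("salvage cycle count must be a positive integer")

    @property
    def salvage_weeks(self) -> int:
        return self.salvage_cycles * self.salvage_cycle_weeks


@dataclass(frozen=True)
class StrategySpec:
    """One comparator strategy: effect sizes, schedule, care mix."""

    name: str
    hr_rfs: HazardRatio = field(default_factory=HazardRatio.fixed)
    hr_os: HazardRatio = field(default_factory=HazardRatio.fixed)
    regimen: Regimen | None = None
    recurrence_care: RecurrenceCare = field(default_factory=RecurrenceCare)


def xelox_regimen(capecitabine_rounding: str = "nearest") -> Regimen:
    """Eight 3-week cycles: oxaliplatin 130 mg/m2 day 1 (IV, per-vial
    billing) + capecitabine 1000 mg/m2 twice daily on days 1-14."""
    return Regimen(
        cycle_length_weeks=3,
        n_cycles=8,
        drugs=(
            DrugComponent(
                "oxaliplatin", 130.0, 50.0, "oxaliplatin_per_50mg", 1, "up"
            ),
            DrugComponent(
                "capecitabine",
                1000.0,
                500.0,
                "capecitabine_per_500mg",
                28,
                capecitabine_rounding,
            ),
        ),
        percycle_cost_keys=("adr_xelox_per_3wk", "hosp_xelox_per_3wk"),
    )


def s1_regimen(s1_rounding: str = "nearest") -> Regimen:
    """Eight 6-week cycles: S-1 40 mg/m2 twice daily, 4 weeks on / 2 off."""
    return Regimen(
        cycle_length_weeks=6,
        n_cycles=8,
        drugs=(
            DrugComponent("s1", 40.0, 20.0, "s1_per_20mg", 56, s1_rounding),
        ),
        percycle_cost_keys=("tests_s1_per_6wk", "adr_s1_per_6wk"),
    )


# ---------------------------------------------------------------------------
# cost streams


def adjuvant_cost_stream(
    strategy: StrategySpec,
    costs: CostTable,
    profile: PatientProfile,
    settings: EconSettings,
    followup_interval_weeks: float = 12.0,
) -> np.ndarray:
    """Weekly cost per patient occupying the RFS state.

    During the adjuvant schedule, drug and per-cycle ancillary costs are
    spread uniformly over each treatment cycle's weeks.  After treatment
    ends (immediately, for surgery only) routine follow-up accrues at one
    follow-up unit per ``followup_interval_weeks``.  Index k holds the
    cost of the cycle spanning [week k, week k+1).
    """
    n = settings.horizon_weeks
    stream = np.zeros(n + 1)
    bsa = profile.bsa
    treat_end = 0
    if strategy.regimen is not None:
        reg = strategy.regimen
        if reg.duration_weeks > n:
            raise ValueError("adjuvant schedule longer than the horizon")
        per_cycle = sum(d.cost_per_cycle(bsa, costs) for d in reg.drugs)
        per_cycle += sum(costs.get(k).median for k in reg.percycle_cost_keys)
        weekly = per_cycle / reg.cycle_length_weeks
        treat_end = reg.duration_weeks
        stream[:treat_end] += weekly
    if followup_interval_weeks > 0:
        followup_weekly = costs.followup_per_unit.median / followup_interval_weeks
        stream[treat_end:] += followup_weekly
    return stream


def recurrence_cost_profile(
    strategy: StrategySpec,
    costs: CostTable,
    n_weeks: int,
) -> np.ndarray:
    """Weekly cost by weeks since entry into the recurrence state.

    During the salvage phase (weeks 1..21 by default) the cohort entrant
    accrues the salvage/supportive mix rate; afterwards everyone is on
    supportive care.  Index 0 is the week of entry itself (no cost);
    index d >= 1 is the d-th week in the state.
    """
    care = strategy.recurrence_care
    salvage_rate = costs.salvage_per_3wk.median / care.salvage_cycle_weeks
    supportive_rate = costs.supportive_per_cycle.median / care.supportive_cycle_weeks
    mix_rate = (
        care.salvage_fraction * salvage_rate
        + care.supportive_fraction * supportive_rate
    )
    profile = np.full(n_weeks + 1, supportive_rate)
    profile[0] = 0.0
    profile[1 : care.salvage_weeks + 1] = mix_rate
    return profile


def _recurrence_cost_stream(
    trace: CohortTrace, profile: np.ndarray, care: RecurrenceCare
) -> np.ndarray:
    """Cohort-level weekly recurrence-state cost.

    The finite salvage-phase excess over supportive care is convolved
    with the new-recurrence inflow; the open-ended supportive-care rate
    is carried by the recurrence occupancy itself, so that patients stop
    accruing cost when they die.
    """
    n = trace.n_cycles
    supportive_rate = profile[-1]
    # entrants arriving at week k spend their first in-state week
    # (d = 1 in the profile) in the cycle starting at week k
    excess = profile[1 : care.salvage_weeks + 1] - supportive_rate
    conv = np.convolve(trace.new_recurrences, excess)[: n + 1]
    return conv + trace.p_rec * supportive_rate


# ---------------------------------------------------------------------------
# accrual and comparison


@dataclass
class CEResult:
    """Discounted lifetime totals for one strategy."""

    name: str
    cost: float
    qalys: float
    cost_rfs: float
    cost_rec: float
    cost_death: float
    life_years: float = 0.0
    residual_alive: float = 0.0
    icer_vs_ref: float | None = None
    icer_sequential: float | None = None
    frontier_status: str = ""

    def as_dict(self) -> dict:
        return {
            "strategy": self.name,
            "total_cost": round(self.cost, 2),
            "qalys": round(self.qalys, 4),
            "cost_rfs": round(self.cost_rfs, 2),
            "cost_rec": round(self.cost_rec, 2),
            "cost_death": round(self.cost_death, 2),
            "icer_vs_ref": None if self.icer_vs_ref is None else round(self.icer_vs_ref, 1),
            "frontier_status": self.frontier_status,
        }


def accrue(
    trace: CohortTrace,
    rfs_stream: np.ndarray,
    rec_profile: np.ndarray,
    utilities: UtilitySet,
    costs: CostTable,
    settings: EconSettings,
    care: RecurrenceCare | None = None,
    name: str = "",
) -> CEResult:
    """Sum discounted costs and QALYs over the trace.

    QALYs accrue as occupancy x utility x cycle length; costs as the
    RFS-state stream weighted by RFS occupancy, the recurrence-care
    stream, and a one-time end-of-life cost per cancer death in its
    cycle of death.
    """
    n = trace.n_cycles
    if len(rfs_stream) != n + 1 or len(rec_profile) != n + 1:
        raise ValueError("cost streams must be on the trace's cycle grid")
    if care is None:
        care = RecurrenceCare()
    disc = trace.discount_factors()
    w = trace.state_weights()
    cycle_years = settings.cycle_length_weeks / WEEKS_PER_YEAR

    qalys = float(
        np.sum(disc * w * (trace.p_rfs * utilities.u_rfs + trace.p_rec * utilities.u_rec))
        * cycle_years
    )
    life_years = float(np.sum(disc * w * (trace.p_rfs + trace.p_rec)) * cycle_years)

    cost_rfs = float(np.sum(disc * w * trace.p_rfs * rfs_stream))
    cost_rec = float(np.sum(disc * w * _recurrence_cost_stream(trace, rec_profile, care)))
    cost_death = float(np.sum(disc * trace.cancer_deaths) * costs.end_of_life.median)

    return CEResult(
        name=name,
        cost=cost_rfs + cost_rec + cost_death,
        qalys=qalys,
        cost_rfs=cost_rfs,
        cost_rec=cost_rec,
        cost_death=cost_death,
        life_years=life_years,
        residual_alive=trace.residual_alive,
    )


def net_monetary_benefit(result: CEResult, reference: CEResult, wtp: float) -> float:
    """Incremental net monetary benefit dE * wtp - dC (dollars)."""
    if wtp <= 0:
        raise ValueError("willingness to pay must be positive")
    return (result.qalys - reference.qalys) * wtp - (result.cost - reference.cost)


def net_health_benefit(result: CEResult, reference: CEResult, wtp: float) -> float:
    """Incremental net health benefit dE - dC / wtp (QALYs)."""
    if wtp <= 0:
        raise ValueError("willingness to pay must be positive")
    return (result.qalys - reference.qalys) - (result.cost - reference.cost) / wtp


def icer_frontier(
    results: Sequence[CEResult], reference: str | None = None
) -> list[CEResult]:
    """Rank strategies, flag dominance, and compute ICERs.

    Strategies are sorted by cost.  A strategy is *dominated* if another
    is at least as effective at no greater cost (strictly better on one
    axis); *extendedly dominated* if its sequential ICER exceeds that of
    a costlier, more effective alternative (i.e. it lies above the
    efficiency frontier's convex hull).  Sequential ICERs are computed
    along the remaining frontier; ``icer_vs_ref`` is the pairwise ICER
    against the designated reference (default: the cheapest strategy).
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies to compare")
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names: {names}")
    ranked = sorted(results, key=lambda r: (r.cost, -r.qalys))

    for r in ranked:
        r.frontier_status = "nondominated"
        r.icer_sequential = None
    # strict dominance
    for r in ranked:
        for other in ranked:
            if other is r:
                continue
            if (
                other.cost <= r.cost
                and other.qalys >= r.qalys
                and (other.cost < r.cost or other.qalys > r.qalys)
            ):
                r.frontier_status = "dominated"
                break
    # extended dominance: iteratively drop frontier points whose
    # sequential ICER exceeds the next one's
    frontier = [r for r in ranked if r.frontier_status == "nondominated"]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = _icer(mid, lo)
            icer_hi = _icer(hi, mid)
            if icer_mid is not None and icer_hi is not None and icer_mid > icer_hi:
                mid.frontier_status = "extendedly dominated"
                frontier.pop(i)
                changed = True
                break
    for prev, cur in zip(frontier, frontier[1:]):
        cur.icer_sequential = _icer(cur, prev)

    ref = ranked[0] if reference is None else next(
        r for r in ranked if r.name == reference
    )
    for r in ranked:
        r.icer_vs_ref = None if r is ref else _icer(r, ref)
    return ranked


def _icer(a: CEResult, b: CEResult) -> float | None:
    de = a.qalys - b.qalys
    dc = a.cost - b.cost
    if de == 0:
        return None
    return dc / de


def results_to_dataframe(results: Sequence[CEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
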