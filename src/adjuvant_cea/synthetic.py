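"""Synthetic patient-level data generators.

The published model is built from aggregate inputs (fitted survival
parameters, cost medians with ranges), not deposited patient-level data.
This module generates the patient-level inputs those aggregates summarize
— event/censoring times drawn from the piecewise Weibull models, and
skewed billing-record costs — so that curve fitting, Kaplan-Meier
estimation, and cost summarization can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import KMPoint

__all__ = [
    "PatientRecord",
    "CostRecord",
    "simulate_event_times",
    "invert_cumulative_hazard",
    "kaplan_meier",
    "generate_cost_records",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient: follow-up time and event indicator."""

    id: int
    time_weeks: float
    event: bool
    arm: str = ""

    def __post_init__(self) -> None:
        if self.time_weeks <= 0:
            raise ValueError("time must be positive")


@dataclass(frozen=True)
class CostRecord:
    """One simulated billing record."""

    id: int
    cost_usd: float
    category: str

    def __post_init__(self) -> None:
        if self.cost_usd < 0:
            raise ValueError("cost must be nonnegative")


def invert_cumulative_hazard(
    curve,
    targets: np.ndarray,
    tol: float = 1e-10,
    t_max: float = 1e6,
) -> np.ndarray:
    """Solve H(t) = target for each target by vectorized bisection.

    H must be nondecreasing with H(0) = 0; the bracket is grown from
    ``[0, 4160]`` weeks until it covers the largest target (capped at
    ``t_max``, where remaining targets saturate).
    """
    targets = np.asarray(targets, dtype=float)
    hi = 4160.0  # 80 years
    while float(curve.cumulative_hazard(hi)) < targets.max() and hi < t_max:
        hi *= 2.0
    hi = min(hi, t_max)
    lo_arr = np.zeros_like(targets)
    hi_arr = np.full_like(targets, hi)
    # bisection to |hi-lo| <= tol
    n_iter = int(np.ceil(np.log2(hi / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo_arr + hi_arr)
        h_mid = np.asarray(curve.cumulative_hazard(mid))
        below = h_mid < targets
        lo_arr = np.where(below, mid, lo_arr)
        hi_arr = np.where(below, hi_arr, mid)
    return 0.5 * (lo_arr + hi_arr)


def simulate_event_times(
    model,
    hr: float,
    n: int,
    censor_time: float,
    seed: int | np.random.Generator,
    arm: str = "",
) -> list[PatientRecord]:
    """Draw event times from a survival model with a hazard ratio applied.

    Inverse-CDF sampling: with U ~ Uniform(0,1), the event time solves
    ``hr * H(t) = -ln(U)``; administrative censoring at ``censor_time``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if censor_time <= 0:
        raise ValueError("censor_time must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    targets = -np.log(u) / hr
    times = invert_cumulative_hazard(model, targets)
    event = times <= censor_time
    times = np.minimum(times, censor_time)
    times = np.maximum(times, 1e-9)
    return [
        PatientRecord(i, float(t), bool(e), arm)
        for i, (t, e) in enumerate(zip(times, event))
    ]


def kaplan_meier(records: list[PatientRecord], grid: np.ndarray) -> list[KMPoint]:
    """Product-limit survival estimate evaluated on a time grid.

    The step function is right-continuous: the estimate at grid time t
    is the product over event times <= t of (1 - d_i / n_i).
    """
    if not any(r.event for r in records):
        raise ValueError("need at least one event to estimate survival")
    times = np.array([r.time_weeks for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    uniq, inverse = np.unique(times, return_inverse=True)
    d = np.bincount(inverse, weights=events.astype(float))
    removed = np.bincount(inverse)
    n_at_risk = len(records) - np.concatenate([[0], np.cumsum(removed)[:-1]])
    factors = 1.0 - d / n_at_risk
    surv_at_uniq = np.cumprod(factors)

    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(uniq, grid, side="right") - 1
    surv = np.where(idx >= 0, surv_at_uniq[np.maximum(idx, 0)], 1.0)
    return [KMPoint(float(t), float(s)) for t, s in zip(grid, surv)]


def generate_cost_records(
    median: float,
    low: float,
    high: float,
    n: int,
    seed: int | np.random.Generator,
    category: str = "salvage",
) -> list[CostRecord]:
    """Simulate skewed billing records with a target median and range.

    Costs are lognormal with mu = ln(median) and sigma chosen so the
    (low, high) range spans the central 95% of the distribution — the
    same parameterization the probabilistic analysis uses for cost
    uncertainty.
    """
    if not (0 < low <= median <= high):
        raise ValueError("require 0 < low <= median <= high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = (np.log(high) - np.log(low)) / (2 * 1.959963984540054)
    draws = np.exp(np.log(median) + sigma * rng.standard_normal(n))
    return [CostRecord(i, float(c), category) for i, c in enumerate(draws)]


def records_to_dataframe(records: list) -> pd.DataFrame:
    """Tabulate patient or cost records for CSV export."""
    if records and isinstance(records[0], PatientRecord):
        return pd.DataFrame(
            {
                "id": [r.id for r in records],
                "time_weeks": [r.time_weeks for r in records],
                "event": [int(r.event) for r in records],
                "arm": [r.arm for r in records],
            }
        )
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "cost_usd": [r.cost_usd for r in records],
            "category": [r.category for r in records],
        }
    )
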