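"""Weekly-cycle cohort trace built from RFS and OS survival curves.

The three health states are relapse-free survival (RFS), disease
recurrence, and death.  State occupancy is partitioned directly from the
two endpoint curves: the RFS curve gives the proportion relapse-free,
one minus the OS curve gives the proportion dead, and the remainder is
in recurrence.  The trace also records the per-cycle decrements (new
recurrences and new deaths) and an attribution of deaths to cancer
versus background causes, which downstream costing needs for the
end-of-life cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import LifeTable

__all__ = [
    "EconSettings",
    "CohortTrace",
    "build_trace",
    "transition_probability",
    "discount_factor",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class EconSettings:
    """Economic evaluation settings.

    The model runs on weekly cycles; the default horizon carries the
    cohort from its starting age to age 100, i.e. a lifetime horizon for
    practical purposes.  Willingness-to-pay anchors are 1x and 3x the
    2012 Chinese per-capita GDP, following the WHO cost-effectiveness
    convention.
    """

    cycle_length_weeks: float = 1.0
    discount_rate: float = 0.03
    start_age: float = 59.5
    horizon_age: float = 100.0
    wtp_1x: float = 6100.0
    wtp_3x: float = 18300.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be nonnegative")
        if self.horizon_weeks < 52:
            raise ValueError("horizon must cover at least one year")
        if self.wtp_1x > self.wtp_3x:
            raise ValueError("wtp_1x must not exceed wtp_3x")

    @property
    def horizon_weeks(self) -> int:
        """Number of weekly cycles to the horizon age."""
        years = self.horizon_age - self.start_age
        return int(round(years * WEEKS_PER_YEAR / self.cycle_length_weeks))


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and decrements (cohort proportions).

    Arrays are indexed by cycle ``k = 0 .. n_cycles``; occupancies are
    taken at the start of cycle ``k`` (time ``k`` weeks), decrement
    arrays hold the flow during cycle ``k`` (zero at ``k = 0``).
    """

    weeks: np.ndarray
    p_rfs: np.ndarray
    p_rec: np.ndarray
    p_dead: np.ndarray
    new_recurrences: np.ndarray
    new_deaths: np.ndarray
    cancer_deaths: np.ndarray
    settings: EconSettings = field(default_factory=EconSettings)

    @property
    def n_cycles(self) -> int:
        return len(self.weeks) - 1

    @property
    def residual_alive(self) -> float:
        """Cohort proportion still alive at the horizon (truncation error)."""
        return float(self.p_rfs[-1] + self.p_rec[-1])

    def discount_factors(self) -> np.ndarray:
        return discount_factor(self.settings, np.arange(len(self.weeks)))

    def state_weights(self) -> np.ndarray:
        """Per-cycle accrual weights over the n+1 grid points.

        Cycle k spans [week k, week k+1); by default its value is taken
        from the state at the cycle start, so the final grid point (the
        horizon itself) carries no weight.  The half-cycle option
        averages start and end states (trapezoid weights).
        """
        w = np.ones(len(self.weeks))
        if self.settings.half_cycle_correction:
            w[0] = w[-1] = 0.5
        else:
            w[-1] = 0.0
        return w

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.weeks)),
                "week": self.weeks,
                "p_rfs": self.p_rfs,
                "p_rec": self.p_rec,
                "p_dead": self.p_dead,
                "new_recurrences": self.new_recurrences,
                "new_deaths": self.new_deaths,
                "discount_factor": self.discount_factors(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def discount_factor(settings: EconSettings, k):
    """Discount factor for cycle ``k``: (1 + r)^(-k * cycle_length / 52)."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("cycle index must be nonnegative")
    years = k_arr * settings.cycle_length_weeks / WEEKS_PER_YEAR
    out = np.power(1.0 + settings.discount_rate, -years)
    return out if np.ndim(k) else float(out)


def transition_probability(curve, k: int, cycle_length_weeks: float = 1.0) -> float:
    """Probability of leaving the curve's state during cycle ``k``.

    1 - S(t_k) / S(t_{k-1}) for the cycle ending at ``t_k = k * cycle
    length``; requires survivors at the start of the cycle.
    """
    if k < 1:
        raise ValueError("cycle index must be >= 1")
    t0 = (k - 1) * cycle_length_weeks
    t1 = k * cycle_length_weeks
    s0 = float(curve.survival(t0))
    s1 = float(curve.survival(t1))
    if s0 <= 0:
        raise ZeroDivisionError("no survivors at the start of the cycle")
    return min(max(1.0 - s1 / s0, 0.0), 1.0)


def build_trace(
    rfs_curve,
    os_curve,
    settings: EconSettings | None = None,
    life_table: LifeTable | None = None,
    death_attribution: str = "excess",
) -> CohortTrace:
    """Partition RFS/OS curves into a weekly three-state occupancy trace.

    ``p_rfs[k] = RFS(t_k)``, ``p_dead[k] = 1 - OS(t_k)`` and
    ``p_rec[k] = OS(t_k) - RFS(t_k)``, clamped at zero (with a warning)
    where extrapolated curves cross.  Decrements:

    * ``new_deaths[k] = OS(t_{k-1}) - OS(t_k)``
    * ``new_recurrences[k]`` = drop in RFS net of the share of deaths
      occurring directly from the RFS state.

    Death attribution splits ``new_deaths`` into cancer deaths (charged
    the end-of-life cost downstream) and background deaths:

    ``"excess"``
        background deaths = RFS occupancy times the life-table weekly
        death probability; the remainder of each cycle's deaths is
        cancer.  Without a life table all deaths count as cancer.
    ``"all"``
        every death is attributed to cancer.
    """
    if settings is None:
        settings = EconSettings()
    if death_attribution not in ("excess", "all"):
        raise ValueError(f"unknown death attribution: {death_attribution!r}")
    n = settings.horizon_weeks
    if n < 1:
        raise ValueError("horizon must cover at least one cycle")
    weeks = np.arange(n + 1, dtype=float) * settings.cycle_length_weeks

    s_rfs = np.asarray(rfs_curve.survival(weeks), dtype=float)
    s_os = np.asarray(os_curve.survival(weeks), dtype=float)
    if np.any(~np.isfinite(s_rfs)) or np.any(~np.isfinite(s_os)):
        raise ValueError("survival curve undefined on the cycle grid")

    p_rec = s_os - s_rfs
    if np.any(p_rec < -1e-12):
        first = int(np.argmax(p_rec < -1e-12))
        warnings.warn(
            f"extrapolated RFS exceeds OS from week {weeks[first]:.0f}; "
            "recurrence occupancy clamped at zero",
            stacklevel=2,
        )
    # where the curves cross, the relapse-free share is capped by OS
    p_rfs = np.minimum(s_rfs, s_os)
    p_rec = np.maximum(p_rec, 0.0)
    p_dead = 1.0 - s_os

    new_deaths = np.concatenate([[0.0], -np.diff(s_os)])
    new_deaths = np.maximum(new_deaths, 0.0)

    # background deaths occurring directly from RFS
    if life_table is not None:
        ages = np.minimum(
            settings.start_age + weeks[:-1] / WEEKS_PER_YEAR,
            life_table.max_age,
        )
        h_bg = life_table.weekly_hazard(ages) * settings.cycle_length_weeks
        q_bg = 1.0 - np.exp(-h_bg)
        bg_deaths = np.concatenate([[0.0], p_rfs[:-1] * q_bg])
        bg_deaths = np.minimum(bg_deaths, new_deaths)
    else:
        bg_deaths = np.zeros_like(new_deaths)

    if death_attribution == "all":
        cancer_deaths = new_deaths.copy()
    else:
        cancer_deaths = np.maximum(new_deaths - bg_deaths, 0.0)

    rfs_drop = np.concatenate([[0.0], -np.diff(p_rfs)])
    new_recurrences = np.maximum(rfs_drop - bg_deaths, 0.0)

    return CohortTrace(
        weeks=weeks,
        p_rfs=p_rfs,
        p_rec=p_rec,
        p_dead=p_dead,
        new_recurrences=new_recurrences,
        new_deaths=new_deaths,
        cancer_deaths=cancer_deaths,
        settings=settings,
    )
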