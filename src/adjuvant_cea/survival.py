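"""Parametric survival curves and their transformations.

The state-occupancy engine is driven entirely by two endpoint survival
curves per strategy: relapse-free survival (RFS) and overall survival
(OS).  The baseline (surgery-only) curves are piecewise Weibull models
with cumulative hazard ``H(t) = scale * t**shape`` on each time segment,
every segment anchored at the time origin.  Treatment curves are derived
by powering the baseline survival with a hazard ratio, and background
(all-cause) mortality from a life table can be blended into the weekly
hazard so that long-run extrapolation never falls below population
mortality.

Time is measured in weeks throughout.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WeibullPiece",
    "PiecewiseWeibull",
    "ProportionalHazardsCurve",
    "GridCurve",
    "HazardRatio",
    "KMPoint",
    "LifeTable",
    "cumulative_hazard",
    "survival",
    "apply_hazard_ratio",
    "fit_piecewise_weibull",
    "blend_background_mortality",
    "default_life_table",
    "gompertz_makeham_life_table",
]

#: Relative jump in cumulative hazard tolerated at an internal breakpoint
#: before a continuity warning is emitted.  Published parameters are
#: rounded, so small jumps are expected.
CONTINUITY_TOL = 0.02


@dataclass(frozen=True)
class WeibullPiece:
    """One segment of a piecewise Weibull model.

    ``scale`` (lambda) and ``shape`` (gamma) parameterize the cumulative
    hazard ``H(t) = scale * t**shape`` with ``t`` in weeks; the piece is
    in force on ``(t_start, t_end]`` but is always evaluated from the
    origin.
    """

    scale: float
    shape: float
    t_start: float
    t_end: float = math.inf

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not self.shape > 0:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if not self.t_start < self.t_end:
            raise ValueError(
                f"t_start ({self.t_start}) must precede t_end ({self.t_end})"
            )

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.scale * np.power(t, self.shape)


@dataclass(frozen=True)
class HazardRatio:
    """Hazard ratio point estimate with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"require 0 < ci_low <= point <= ci_high, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )

    @classmethod
    def fixed(cls, value: float = 1.0) -> "HazardRatio":
        return cls(value, value, value)


@dataclass(frozen=True)
class KMPoint:
    """A (time, survival) point read off a Kaplan-Meier curve."""

    time: float
    survival: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be nonnegative")
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival must lie in [0, 1]")


class PiecewiseWeibull:
    """Piecewise Weibull survival model, each piece anchored at t = 0.

    Parameters
    ----------
    pieces:
        Ordered, contiguous segments covering (0, inf).  At an internal
        breakpoint the earlier piece applies.
    endpoint:
        Label for reporting ("RFS" or "OS").
    """

    def __init__(self, pieces: Sequence[WeibullPiece], endpoint: str = ""):
        pieces = sorted(pieces, key=lambda p: p.t_start)
        if not pieces:
            raise ValueError("at least one piece is required")
        if pieces[0].t_start != 0:
            raise ValueError("first piece must start at t = 0")
        if not math.isinf(pieces[-1].t_end):
            raise ValueError("last piece must extend to infinity")
        for a, b in zip(pieces, pieces[1:]):
            if a.t_end != b.t_start:
                raise ValueError(
                    f"pieces must be contiguous: {a.t_end} != {b.t_start}"
                )
        self.pieces = tuple(pieces)
        self.endpoint = endpoint
        # internal breakpoints; piece i applies for t in (bp[i-1], bp[i]]
        self._breaks = np.array([p.t_end for p in pieces[:-1]])
        self._check_continuity()

    def _check_continuity(self) -> None:
        for a, b in zip(self.pieces, self.pieces[1:]):
            t = a.t_end
            ha = float(a.cumulative_hazard(t))
            hb = float(b.cumulative_hazard(t))
            if ha > 0 and abs(ha - hb) / ha > CONTINUITY_TOL:
                warnings.warn(
                    f"cumulative hazard jumps {abs(ha - hb) / ha:.1%} at "
                    f"t={t} weeks ({self.endpoint or 'curve'}); pieces may "
                    "be inconsistent",
                    stacklevel=3,
                )

    def _piece_index(self, t: np.ndarray) -> np.ndarray:
        # left-closed at breakpoints: at t == break the earlier piece applies
        return np.searchsorted(self._breaks, t, side="left")

    def cumulative_hazard(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be nonnegative")
        idx = self._piece_index(t_arr)
        scale = np.array([p.scale for p in self.pieces])[idx]
        shape = np.array([p.shape for p in self.pieces])[idx]
        with np.errstate(divide="ignore"):
            h = scale * np.power(t_arr, shape)
        h = np.where(t_arr == 0, 0.0, h)
        return h if np.ndim(t) else float(h)

    def survival(self, t):
        return np.exp(-np.asarray(self.cumulative_hazard(t))) if np.ndim(t) \
            else math.exp(-self.cumulative_hazard(t))

    def hazard(self, t):
        """Instantaneous hazard dH/dt (vectorized)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be nonnegative")
        idx = self._piece_index(t_arr)
        scale = np.array([p.scale for p in self.pieces])[idx]
        shape = np.array([p.shape for p in self.pieces])[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = scale * shape * np.power(t_arr, shape - 1.0)
        h = np.nan_to_num(h, posinf=0.0)
        return h if np.ndim(t) else float(h)

    def __repr__(self) -> str:
        segs = ", ".join(
            f"[{p.t_start:g},{p.t_end:g}): lam={p.scale:g}, gam={p.shape:g}"
            for p in self.pieces
        )
        return f"PiecewiseWeibull({self.endpoint or 'curve'}; {segs})"


class ProportionalHazardsCurve:
    """Baseline curve with a hazard ratio applied: S(t) = S0(t)**hr."""

    def __init__(self, base, hr: float):
        if not hr > 0:
            raise ValueError("hazard ratio must be positive")
        self.base = base
        self.hr = float(hr)
        self.endpoint = getattr(base, "endpoint", "")

    def cumulative_hazard(self, t):
        return self.hr * np.asarray(self.base.cumulative_hazard(t))

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))


class GridCurve:
    """Survival curve tabulated on a weekly grid (linear interpolation).

    Produced by :func:`blend_background_mortality`; outside the grid the
    last value is held.
    """

    def __init__(self, weeks: np.ndarray, surv: np.ndarray, endpoint: str = ""):
        weeks = np.asarray(weeks, dtype=float)
        surv = np.asarray(surv, dtype=float)
        if weeks.shape != surv.shape or weeks.ndim != 1:
            raise ValueError("weeks and survival must be matching 1-D arrays")
        if np.any(np.diff(weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        self.weeks = weeks
        self.surv = surv
        self.endpoint = endpoint

    def survival(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be nonnegative")
        out = np.interp(t_arr, self.weeks, self.surv)
        return out if np.ndim(t) else float(out)

    def cumulative_hazard(self, t):
        s = np.asarray(self.survival(t))
        with np.errstate(divide="ignore"):
            h = -np.log(s)
        return h if np.ndim(t) else float(h)


# ---------------------------------------------------------------------------
# functional API


def cumulative_hazard(model, t):
    """Cumulative hazard H(t) of any curve object at time ``t`` (weeks)."""
    return model.cumulative_hazard(t)


def survival(model, t):
    """Survival probability S(t) = exp(-H(t))."""
    return model.survival(t)


def apply_hazard_ratio(model, hr: float) -> ProportionalHazardsCurve:
    """Scale a curve's hazard by ``hr`` (proportional hazards).

    ``hr == 1`` returns a curve numerically identical to the baseline.
    """
    return ProportionalHazardsCurve(model, hr)


# ---------------------------------------------------------------------------
# fitting


def fit_piecewise_weibull(
    points: Iterable[KMPoint],
    breakpoint: float,
    endpoint: str = "",
) -> tuple[PiecewiseWeibull, list[float]]:
    """Fit a two-piece Weibull model to Kaplan-Meier points.

    On each segment ``ln(-ln S)`` is regressed on ``ln t`` by unweighted
    least squares; the slope is the shape and the intercept is the log
    scale.  Points at ``S == 0`` or ``S == 1`` carry no information on
    the transformed scale and are dropped with a warning.

    Parameters
    ----------
    points:
        Kaplan-Meier points (time in weeks, survival).
    breakpoint:
        The time splitting the two segments; points with ``t <= breakpoint``
        go to the first segment.

    Returns
    -------
    (model, r2):
        The fitted :class:`PiecewiseWeibull` and the per-segment
        coefficient of determination on the ``ln(-ln S) ~ ln t`` scale.
    """
    pts = [p if isinstance(p, KMPoint) else KMPoint(*p) for p in points]
    usable = [p for p in pts if 0.0 < p.survival < 1.0 and p.time > 0]
    dropped = len(pts) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} point(s) with S=0, S=1 or t=0 from the fit",
            stacklevel=2,
        )
    segments = (
        [p for p in usable if p.time <= breakpoint],
        [p for p in usable if p.time > breakpoint],
    )
    pieces: list[WeibullPiece] = []
    r2s: list[float] = []
    bounds = [(0.0, float(breakpoint)), (float(breakpoint), math.inf)]
    for seg, (lo, hi) in zip(segments, bounds):
        if len(seg) < 3:
            raise ValueError(
                f"segment ({lo}, {hi}] has {len(seg)} usable points; "
                "need at least 3"
            )
        x = np.log([p.time for p in seg])
        y = np.log(-np.log([p.survival for p in seg]))
        shape, logscale = np.polyfit(x, y, 1)
        resid = y - (shape * x + logscale)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        pieces.append(WeibullPiece(math.exp(logscale), shape, lo, hi))
        r2s.append(r2)
    return PiecewiseWeibull(pieces, endpoint=endpoint), r2s


# ---------------------------------------------------------------------------
# life tables and background mortality


class LifeTable:
    """Annual death probabilities q_x by single year of age."""

    def __init__(self, ages: Sequence[float], qx: Sequence[float]):
        ages_arr = np.asarray(ages, dtype=float)
        qx_arr = np.asarray(qx, dtype=float)
        if ages_arr.shape != qx_arr.shape or ages_arr.ndim != 1:
            raise ValueError("ages and qx must be matching 1-D arrays")
        if np.any(np.diff(ages_arr) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((qx_arr < 0) | (qx_arr > 1)):
            raise ValueError("q_x values must lie in [0, 1]")
        if qx_arr[-1] != 1.0:
            raise ValueError("terminal q_x must equal 1 at the maximum age")
        self.ages = ages_arr
        self.qx = qx_arr

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def annual_q(self, age) -> np.ndarray:
        """q_x for the age band containing ``age`` (floor lookup)."""
        age_arr = np.asarray(age, dtype=float)
        if np.any(age_arr < self.ages[0]):
            raise ValueError("age below the life table range")
        idx = np.minimum(
            np.searchsorted(self.ages, age_arr, side="right") - 1,
            len(self.ages) - 1,
        )
        return self.qx[idx]

    def weekly_hazard(self, age) -> np.ndarray:
        """Constant weekly background hazard within the age band.

        h_b = -ln(1 - q_x) / 52; a terminal q_x of 1 is clipped so the
        hazard stays finite.
        """
        q = np.clip(self.annual_q(age), 0.0, 1.0 - 1e-12)
        return -np.log1p(-q) / 52.0

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        ages, qx = [], []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {
                "age_years",
                "qx",
            } - set(reader.fieldnames):
                raise ValueError(
                    f"{path}: expected header 'age_years,qx', "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                ages.append(float(row["age_years"]))
                qx.append(float(row["qx"]))
        return cls(ages, qx)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["age_years", "qx"])
            for a, q in zip(self.ages, self.qx):
                writer.writerow([f"{a:g}", f"{q:.6g}"])


def gompertz_makeham_life_table(
    makeham: float = 5e-4,
    gompertz_b: float = 4.14e-5,
    gompertz_c: float = 0.092,
    max_age: int = 100,
) -> LifeTable:
    """Synthetic life table with hazard mu(x) = A + B*exp(C*x).

    The default constants give a period life expectancy at birth of about
    76 years, in the range of the general population the cohort is drawn
    from.  The terminal age closes the table with q_x = 1.
    """
    ages = np.arange(0, max_age + 1, dtype=float)
    annual_h = makeham + gompertz_b * (
        np.exp(gompertz_c * (ages + 1)) - np.exp(gompertz_c * ages)
    ) / gompertz_c
    qx = 1.0 - np.exp(-annual_h)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def default_life_table() -> LifeTable:
    """The life table shipped with the package (synthetic, see data/)."""
    path = Path(__file__).parent / "data" / "life_table_synthetic.csv"
    if path.exists():
        return LifeTable.from_csv(path)
    return gompertz_makeham_life_table()


def blend_background_mortality(
    os_curve,
    rfs_curve,
    life_table: LifeTable,
    start_age: float,
    mode: str = "max",
    from_week: float = 0.0,
    horizon_weeks: int = 2106,
):
    """Blend population mortality from a life table into both curves.

    Weekly hazard increments of each curve are compared with the
    background weekly hazard implied by the life table at the cohort's
    attained age.  Modes:

    ``"max"``
        total weekly hazard = max(disease-model hazard, background hazard),
        applied from ``from_week`` onward (default: from the start).
    ``"additive"``
        background hazard is added on top of the model hazard from
        ``from_week`` onward (use the trial follow-up horizon to keep the
        observed period untouched).
    ``"off"``
        curves returned unchanged (as :class:`GridCurve` on the grid).

    Returns ``(os_adj, rfs_adj)`` as :class:`GridCurve` objects on a
    weekly grid of ``horizon_weeks`` cycles.
    """
    if mode not in ("max", "additive", "off"):
        raise ValueError(f"unknown background-mortality mode: {mode!r}")
    weeks = np.arange(horizon_weeks + 1, dtype=float)
    ages = start_age + weeks[:-1] / 52.0
    if np.any(ages < life_table.ages[0]) or start_age > life_table.max_age:
        raise ValueError("start_age outside the life table range")
    # ages beyond the table's terminal band reuse the terminal q_x
    ages = np.minimum(ages, life_table.max_age)
    h_bg = life_table.weekly_hazard(ages)
    active = weeks[:-1] >= from_week

    out = []
    for curve in (os_curve, rfs_curve):
        ch = np.asarray(curve.cumulative_hazard(weeks), dtype=float)
        dh = np.diff(ch)
        if mode == "max":
            dh = np.where(active, np.maximum(dh, h_bg), dh)
        elif mode == "additive":
            dh = np.where(active, dh + h_bg, dh)
        surv = np.exp(-np.concatenate([[0.0], np.cumsum(dh)]))
        out.append(GridCurve(weeks, surv, endpoint=getattr(curve, "endpoint", "")))
    return out[0], out[1]
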