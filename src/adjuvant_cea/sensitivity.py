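"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the deterministic pipeline with each
parameter at the bounds of its published range and reports the
incremental net health benefit of the intervention versus the reference
at the willingness-to-pay threshold.  Probabilistic analysis samples
every uncertain parameter from its distribution — lognormal for costs,
beta for utilities, normal-on-log-scale for hazard ratios — re-runs the
cohort pipeline per iteration, and summarizes cost-effectiveness
acceptability across a willingness-to-pay grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTrace, EconSettings
from .config import AnalysisConfig
from .economics import net_health_benefit
from .pipeline import evaluate_strategy, strategy_curves
from .survival import HazardRatio
from .synthetic import invert_cumulative_hazard

__all__ = [
    "ParamRange",
    "PSAOutput",
    "build_param_ranges",
    "apply_param",
    "build_distribution",
    "one_way",
    "tornado",
    "run_psa",
    "ceac",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ParamRange:
    """An uncertain parameter: base value, range, and distribution family."""

    name: str
    base: float
    low: float
    high: float
    dist: str  # lognormal | beta | loghr-normal | fixed

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.dist not in ("lognormal", "beta", "loghr-normal", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist == "beta" and not (0 < self.base < 1):
            raise ValueError(f"{self.name}: beta requires base in (0, 1)")
        if self.dist in ("lognormal", "loghr-normal") and self.low <= 0:
            raise ValueError(f"{self.name}: log-scale family requires positive bounds")


# ---------------------------------------------------------------------------
# parameter registry


def build_param_ranges(config: AnalysisConfig, analysis: str = "psa") -> list[ParamRange]:
    """Enumerate the uncertain parameters of a configuration.

    ``analysis="psa"`` lists the sampled parameters (costs, utilities,
    hazard ratios); ``analysis="owsa"`` additionally includes structural
    knobs varied deterministically (discount rate, follow-up cadence).
    """
    if analysis not in ("psa", "owsa"):
        raise ValueError(f"unknown analysis kind: {analysis!r}")
    params: list[ParamRange] = []
    for key in config.costs.keys():
        item = config.costs.get(key)
        if item.low == item.high:
            continue  # fixed price
        params.append(
            ParamRange(f"cost.{key}", item.median, item.low, item.high, "lognormal")
        )
    u = config.utilities
    params.append(ParamRange("u_rfs", u.u_rfs, *u.u_rfs_range, "beta"))
    params.append(ParamRange("u_rec", u.u_rec, *u.u_rec_range, "beta"))
    for s in config.strategies:
        for label, hr in (("hr_rfs", s.hr_rfs), ("hr_os", s.hr_os)):
            if hr.ci_low == hr.ci_high:
                continue  # reference strategy, HR pinned at 1
            params.append(
                ParamRange(
                    f"{label}.{s.name}", hr.point, hr.ci_low, hr.ci_high, "loghr-normal"
                )
            )
    if analysis == "owsa":
        params.append(
            ParamRange(
                "discount_rate",
                config.settings.discount_rate,
                *config.discount_range,
                "fixed",
            )
        )
        params.append(
            ParamRange(
                "followup_interval_weeks",
                config.followup_interval_weeks,
                *config.followup_interval_range,
                "fixed",
            )
        )
    return sorted(params, key=lambda p: p.name)


def apply_param(config: AnalysisConfig, name: str, value: float) -> AnalysisConfig:
    """Return a copy of the configuration with one parameter replaced."""
    if name.startswith("cost."):
        key = name[len("cost.") :]
        return config.replace(costs=config.costs.with_value(key, value))
    if name == "u_rfs":
        return config.replace(
            utilities=dataclasses.replace(config.utilities, u_rfs=float(value))
        )
    if name == "u_rec":
        return config.replace(
            utilities=dataclasses.replace(config.utilities, u_rec=float(value))
        )
    if name.startswith("hr_rfs.") or name.startswith("hr_os."):
        which, strat_name = name.split(".", 1)
        strategy = config.strategy(strat_name)
        return config.with_strategy(
            dataclasses.replace(strategy, **{which: HazardRatio.fixed(float(value))})
        )
    if name == "discount_rate":
        return config.replace(
            settings=dataclasses.replace(config.settings, discount_rate=float(value))
        )
    if name == "followup_interval_weeks":
        return config.replace(followup_interval_weeks=float(value))
    raise KeyError(f"unknown parameter: {name!r}")


# ---------------------------------------------------------------------------
# distributions


class _Sampler:
    def __init__(self, kind: str, **kw):
        self.kind = kind
        self.kw = kw

    def sample(self, rng: np.random.Generator, size=None):
        kw = self.kw
        if self.kind == "degenerate":
            value = kw["value"]
            return value if size is None else np.full(size, value)
        if self.kind == "lognormal":
            z = rng.standard_normal(size)
            return np.exp(kw["mu"] + kw["sigma"] * z)
        if self.kind == "beta":
            draw = rng.beta(kw["a"], kw["b"], size)
            return np.clip(draw, 1e-9, 1 - 1e-9)
        raise AssertionError(self.kind)


def build_distribution(param: ParamRange) -> _Sampler:
    """Sampling distribution for a parameter.

    * lognormal and loghr-normal: median at the base value, the (low,
      high) range read as the central 95% interval on the log scale;
    * beta: moment-matched to mean = base and sd = (high - low) / (2 x 1.96);
    * fixed: degenerate at the base value.
    """
    if param.dist == "fixed" or param.low == param.high:
        return _Sampler("degenerate", value=param.base)
    if param.dist in ("lognormal", "loghr-normal"):
        sigma = (np.log(param.high) - np.log(param.low)) / (2 * Z95)
        return _Sampler("lognormal", mu=np.log(param.base), sigma=sigma)
    if param.dist == "beta":
        mean = param.base
        sd = (param.high - param.low) / (2 * Z95)
        var = min(sd**2, mean * (1 - mean) * 0.999)
        nu = mean * (1 - mean) / var - 1.0
        return _Sampler("beta", a=mean * nu, b=(1 - mean) * nu)
    raise AssertionError(param.dist)


# ---------------------------------------------------------------------------
# one-way (tornado)


def _incremental(config: AnalysisConfig, wtp: float) -> dict:
    _, res_int = evaluate_strategy(config, config.strategy(config.intervention))
    _, res_ref = evaluate_strategy(config, config.strategy(config.reference))
    de = res_int.qalys - res_ref.qalys
    dc = res_int.cost - res_ref.cost
    return {
        "nhb": net_health_benefit(res_int, res_ref, wtp),
        "icer": dc / de if de != 0 else np.nan,
        "d_qalys": de,
        "d_cost": dc,
    }


def one_way(
    config: AnalysisConfig, param: ParamRange, wtp: float | None = None
) -> tuple[float, float]:
    """Incremental NHB (intervention vs reference) with the parameter at
    its low and high bound, everything else at base."""
    if wtp is None:
        wtp = config.settings.wtp_1x
    lo = _incremental(apply_param(config, param.name, param.low), wtp)
    hi = _incremental(apply_param(config, param.name, param.high), wtp)
    return lo["nhb"], hi["nhb"]


def tornado(
    config: AnalysisConfig, wtp: float | None = None
) -> pd.DataFrame:
    """One-way sensitivity of incremental NHB to every OWSA parameter.

    Rows are sorted by bar width |NHB(high) - NHB(low)| descending; the
    ICER of the intervention versus the reference at each bound is
    reported alongside.
    """
    if wtp is None:
        wtp = config.settings.wtp_1x
    rows = []
    for param in build_param_ranges(config, analysis="owsa"):
        lo = _incremental(apply_param(config, param.name, param.low), wtp)
        hi = _incremental(apply_param(config, param.name, param.high), wtp)
        rows.append(
            {
                "parameter": param.name,
                "low": param.low,
                "high": param.high,
                "nhb_low": lo["nhb"],
                "nhb_high": hi["nhb"],
                "width": abs(hi["nhb"] - lo["nhb"]),
                "icer_low": lo["icer"],
                "icer_high": hi["icer"],
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("width", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAOutput:
    """Per-iteration (cost, QALY) draws and the derived CEAC."""

    strategies: list[str]
    costs: np.ndarray  # (n_iter, n_strategies)
    qalys: np.ndarray  # (n_iter, n_strategies)
    wtp_grid: np.ndarray
    ceac: np.ndarray  # (len(wtp_grid), n_strategies)
    reference: str
    seed: int

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for j, name in enumerate(self.strategies):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iter),
                        "strategy": name,
                        "cost": self.costs[:, j],
                        "qalys": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def ceac_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ceac, columns=self.strategies)
        df.insert(0, "wtp", self.wtp_grid)
        return df

    def incremental_scatter(self, strategy: str) -> pd.DataFrame:
        """(dQALY, dCost) draws of a strategy versus the reference."""
        j = self.strategies.index(strategy)
        r = self.strategies.index(self.reference)
        return pd.DataFrame(
            {
                "d_qalys": self.qalys[:, j] - self.qalys[:, r],
                "d_cost": self.costs[:, j] - self.costs[:, r],
            }
        )

    def probability_cost_effective(self, strategy: str, wtp: float) -> float:
        """CEAC value for one strategy at one threshold (nearest grid point)."""
        i = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.ceac[i, self.strategies.index(strategy)])


def _empirical_trace(
    config: AnalysisConfig, strategy, n_patients: int, rng: np.random.Generator
) -> CohortTrace:
    """First-order (microsimulation) trace: occupancy from simulated
    patients instead of expected cohort proportions."""
    from .cohort import build_trace
    from .survival import GridCurve

    rfs_curve, os_curve = strategy_curves(config, strategy)
    u = rng.uniform(size=n_patients)
    targets = -np.log(u)
    t_rfs = invert_cumulative_hazard(rfs_curve, targets)
    t_os = invert_cumulative_hazard(os_curve, targets)
    t_os = np.maximum(t_os, t_rfs)
    weeks = np.arange(config.settings.horizon_weeks + 1, dtype=float)
    emp_rfs = (t_rfs[None, :] > weeks[:, None]).mean(axis=1)
    emp_os = (t_os[None, :] > weeks[:, None]).mean(axis=1)
    life_table = config.life_table if config.background_mode != "off" else None
    return build_trace(
        GridCurve(weeks, emp_rfs, "RFS"),
        GridCurve(weeks, emp_os, "OS"),
        config.settings,
        life_table=life_table,
        death_attribution=config.death_attribution,
    )


def run_psa(
    config: AnalysisConfig,
    n_iter: int | None = None,
    seed: int | None = None,
    wtp_grid: np.ndarray | None = None,
    first_order_patients: int = 0,
) -> PSAOutput:
    """Second-order PSA around the deterministic cohort engine.

    Each iteration draws every uncertain parameter (in sorted-name
    order, from a single seeded generator), rebuilds the configuration,
    and evaluates all strategies deterministically.  With
    ``first_order_patients > 0`` state occupancy is additionally
    resampled from that many simulated patients per iteration
    (first-order uncertainty; off by default).
    """
    if n_iter is None:
        n_iter = config.psa_iterations
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if seed is None:
        seed = config.seed
    if wtp_grid is None:
        wtp_grid = config.wtp_grid
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size < 1:
        raise ValueError("willingness-to-pay grid is empty")

    params = build_param_ranges(config, analysis="psa")
    samplers = {p.name: build_distribution(p) for p in params}
    rng = np.random.default_rng(seed)
    names = [s.name for s in config.strategies]
    costs = np.empty((n_iter, len(names)))
    qalys = np.empty((n_iter, len(names)))

    for it in range(n_iter):
        cfg = config
        for p in params:  # already sorted by name
            cfg = apply_param(cfg, p.name, float(samplers[p.name].sample(rng)))
        for j, strat_name in enumerate(names):
            strategy = cfg.strategy(strat_name)
            if first_order_patients > 0:
                from .economics import accrue, adjuvant_cost_stream, recurrence_cost_profile

                trace = _empirical_trace(cfg, strategy, first_order_patients, rng)
                stream = adjuvant_cost_stream(
                    strategy,
                    cfg.costs,
                    cfg.profile,
                    cfg.settings,
                    followup_interval_weeks=cfg.followup_interval_weeks,
                )
                profile = recurrence_cost_profile(
                    strategy, cfg.costs, cfg.settings.horizon_weeks
                )
                result = accrue(
                    trace,
                    stream,
                    profile,
                    cfg.utilities,
                    cfg.costs,
                    cfg.settings,
                    care=strategy.recurrence_care,
                    name=strat_name,
                )
            else:
                _, result = evaluate_strategy(cfg, strategy)
            costs[it, j] = result.cost
            qalys[it, j] = result.qalys

    out = PSAOutput(
        strategies=names,
        costs=costs,
        qalys=qalys,
        wtp_grid=wtp_grid,
        ceac=np.empty((len(wtp_grid), len(names))),
        reference=config.reference,
        seed=seed,
    )
    out.ceac = ceac(out, wtp_grid)
    return out


def ceac(psa: PSAOutput, wtp_grid: np.ndarray) -> np.ndarray:
    """Cost-effectiveness acceptability: P(strategy maximizes net
    monetary benefit) at each threshold, ties split equally."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size < 1:
        raise ValueError("willingness-to-pay grid is empty")
    if psa.costs.shape[0] < 1:
        raise ValueError("need at least one PSA iteration")
    out = np.empty((len(wtp_grid), len(psa.strategies)))
    for i, wtp in enumerate(wtp_grid):
        nmb = psa.qalys * wtp - psa.costs  # (n_iter, S)
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = winners / winners.sum(axis=1, keepdims=True)
        out[i] = weights.mean(axis=0)
    return out
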