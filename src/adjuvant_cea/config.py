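"""Analysis configuration: schema, validation, and the bundled base case.

A configuration gathers everything a run needs: the baseline survival
models, the comparator strategies with their hazard ratios and
schedules, unit costs, utilities, economic settings, background
mortality handling, and sensitivity-analysis settings.  The bundled
``data/basecase.yaml`` holds the published base-case inputs and is the
default for every entry point.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import EconSettings
from .economics import (
    CostItem,
    CostTable,
    DrugComponent,
    PatientProfile,
    RecurrenceCare,
    Regimen,
    StrategySpec,
    UtilitySet,
    s1_regimen,
    xelox_regimen,
)
from .survival import (
    HazardRatio,
    LifeTable,
    PiecewiseWeibull,
    WeibullPiece,
    default_life_table,
)

__all__ = [
    "AnalysisConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "default_config_path",
]

DATA_DIR = Path(__file__).parent / "data"


class ConfigError(ValueError):
    """Configuration validation failure, pointing at the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


@dataclass
class SurvivalCheck:
    """One model-vs-reference survival comparison for the validation report."""

    strategy: str
    endpoint: str  # "RFS" | "OS"
    years: float
    expected_pct: float
    trial_pct: float | None = None


@dataclass
class AnalysisConfig:
    """Fully resolved inputs for one analysis run."""

    base_rfs: PiecewiseWeibull
    base_os: PiecewiseWeibull
    strategies: tuple[StrategySpec, ...]
    reference: str
    intervention: str
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    profile: PatientProfile = field(default_factory=PatientProfile)
    settings: EconSettings = field(default_factory=EconSettings)
    life_table: LifeTable = field(default_factory=default_life_table)
    background_mode: str = "additive"
    background_from_week: float = 260.0
    death_attribution: str = "excess"
    followup_interval_weeks: float = 12.0
    psa_iterations: int = 1000
    seed: int = 20130101
    wtp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 20001.0, 500.0)
    )
    discount_range: tuple[float, float] = (0.0, 0.06)
    followup_interval_range: tuple[float, float] = (6.0, 26.0)
    validation: tuple[SurvivalCheck, ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ConfigError("strategies", f"duplicate names: {names}")
        if self.reference not in names:
            raise ConfigError(
                "reference", f"{self.reference!r} not among strategies {names}"
            )
        if self.intervention not in names:
            raise ConfigError(
                "intervention",
                f"{self.intervention!r} not among strategies {names}",
            )
        if self.background_mode not in ("max", "additive", "off"):
            raise ConfigError("background_mortality.mode", self.background_mode)

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def with_strategy(self, strategy: StrategySpec) -> "AnalysisConfig":
        strategies = tuple(
            strategy if s.name == strategy.name else s for s in self.strategies
        )
        return self.replace(strategies=strategies)


# ---------------------------------------------------------------------------
# YAML loading


def _require(mapping: dict, key: str, path: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigError(f"{path}.{key}", "missing required key")
    return mapping[key]


def _positive(value, path: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ConfigError(path, f"not a number: {value!r}") from None
    if v <= 0:
        raise ConfigError(path, f"must be positive, got {v}")
    return v


def _parse_pieces(spec: list, path: str, endpoint: str) -> PiecewiseWeibull:
    if not isinstance(spec, list) or not spec:
        raise ConfigError(path, "expected a non-empty list of pieces")
    pieces = []
    for i, p in enumerate(spec):
        here = f"{path}[{i}]"
        t_end = p.get("t_end", math.inf)
        t_end = math.inf if t_end in (None, ".inf", "inf") else float(t_end)
        try:
            pieces.append(
                WeibullPiece(
                    scale=_positive(_require(p, "scale", here), f"{here}.scale"),
                    shape=_positive(_require(p, "shape", here), f"{here}.shape"),
                    t_start=float(_require(p, "t_start", here)),
                    t_end=t_end,
                )
            )
        except ValueError as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(here, str(exc)) from None
    try:
        return PiecewiseWeibull(pieces, endpoint=endpoint)
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from None


def _parse_hr(spec, path: str) -> HazardRatio:
    if spec is None:
        raise ConfigError(path, "strategy is missing a hazard ratio")
    if isinstance(spec, (int, float)):
        return HazardRatio.fixed(float(spec))
    try:
        return HazardRatio(
            point=float(_require(spec, "point", path)),
            ci_low=float(_require(spec, "ci_low", path)),
            ci_high=float(_require(spec, "ci_high", path)),
        )
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(path, str(exc)) from None


def _parse_regimen(spec, path: str, costing: dict) -> Regimen | None:
    if spec in (None, "none"):
        return None
    if spec == "xelox":
        return xelox_regimen(costing.get("capecitabine_rounding", "nearest"))
    if spec == "s1":
        return s1_regimen(costing.get("s1_rounding", "nearest"))
    if not isinstance(spec, dict):
        raise ConfigError(path, f"unknown regimen: {spec!r}")
    drugs = []
    for i, d in enumerate(_require(spec, "drugs", path)):
        here = f"{path}.drugs[{i}]"
        rounding = d.get("rounding", "up")
        if rounding not in ("up", "nearest"):
            raise ConfigError(f"{here}.rounding", f"unknown mode {rounding!r}")
        drugs.append(
            DrugComponent(
                name=str(_require(d, "name", here)),
                dose_mg_per_m2=_positive(
                    _require(d, "dose_mg_per_m2", here), f"{here}.dose_mg_per_m2"
                ),
                unit_size_mg=_positive(
                    _require(d, "unit_size_mg", here), f"{here}.unit_size_mg"
                ),
                cost_key=str(_require(d, "cost_key", here)),
                administrations_per_cycle=int(
                    _require(d, "administrations_per_cycle", here)
                ),
                rounding=rounding,
            )
        )
    return Regimen(
        cycle_length_weeks=int(_require(spec, "cycle_length_weeks", path)),
        n_cycles=int(_require(spec, "n_cycles", path)),
        drugs=tuple(drugs),
        percycle_cost_keys=tuple(spec.get("percycle_cost_keys", ())),
    )


def _parse_costs(spec: dict, path: str) -> CostTable:
    table = CostTable()
    if not spec:
        return table
    known = set(table.keys())
    overrides = {}
    for key, val in spec.items():
        here = f"{path}.{key}"
        if key not in known:
            raise ConfigError(here, "unknown cost item")
        if isinstance(val, (int, float)):
            overrides[key] = CostItem.fixed(float(val))
            continue
        median = float(_require(val, "median", here))
        low = float(val.get("low", median))
        high = float(val.get("high", median))
        try:
            overrides[key] = CostItem(median, low, high)
        except ValueError as exc:
            raise ConfigError(here, str(exc)) from None
    return dataclasses.replace(table, **overrides)


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(str(path), "file not found")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(str(path), "top level must be a mapping")
    return build_config(raw, base_dir=path.parent)


def build_config(raw: dict, base_dir: Path | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a parsed mapping."""
    models = _require(raw, "survival_models", "")
    base_rfs = _parse_pieces(
        _require(models, "rfs", "survival_models"), "survival_models.rfs", "RFS"
    )
    base_os = _parse_pieces(
        _require(models, "os", "survival_models"), "survival_models.os", "OS"
    )

    costing = raw.get("costing", {}) or {}
    care_spec = costing.get("recurrence_care", {}) or {}
    try:
        care = RecurrenceCare(
            salvage_fraction=float(care_spec.get("salvage_fraction", 0.865)),
            supportive_fraction=float(care_spec.get("supportive_fraction", 0.135)),
            salvage_cycles=int(care_spec.get("salvage_cycles", 7)),
        )
    except ValueError as exc:
        raise ConfigError("costing.recurrence_care", str(exc)) from None

    strategies = []
    for i, s in enumerate(_require(raw, "strategies", "")):
        here = f"strategies[{i}]"
        name = str(_require(s, "name", here))
        strategies.append(
            StrategySpec(
                name=name,
                hr_rfs=_parse_hr(s.get("hr_rfs"), f"{here}.hr_rfs"),
                hr_os=_parse_hr(s.get("hr_os"), f"{here}.hr_os"),
                regimen=_parse_regimen(s.get("regimen"), f"{here}.regimen", costing),
                recurrence_care=care,
            )
        )

    costs = _parse_costs(raw.get("costs", {}) or {}, "costs")
    for i, s in enumerate(strategies):
        if s.regimen is None:
            continue
        for d in s.regimen.drugs:
            try:
                costs.get(d.cost_key)
            except KeyError:
                raise ConfigError(
                    f"strategies[{i}].regimen", f"unresolvable cost key {d.cost_key!r}"
                ) from None

    util_spec = raw.get("utilities", {}) or {}
    try:
        utilities = UtilitySet(
            u_rfs=float(util_spec.get("u_rfs", 0.88)),
            u_rec=float(util_spec.get("u_rec", 0.42)),
            u_rfs_range=tuple(util_spec.get("u_rfs_range", (0.80, 0.97))),
            u_rec_range=tuple(util_spec.get("u_rec_range", (0.28, 0.63))),
        )
    except ValueError as exc:
        raise ConfigError("utilities", str(exc)) from None

    prof_spec = raw.get("patient", {}) or {}
    profile = PatientProfile(
        weight_kg=float(prof_spec.get("weight_kg", 65.0)),
        height_m=float(prof_spec.get("height_m", 1.64)),
    )
    if "bsa" in prof_spec:
        if abs(profile.bsa - float(prof_spec["bsa"])) / float(prof_spec["bsa"]) > 0.005:
            raise ConfigError(
                "patient.bsa",
                f"inconsistent with Mosteller BSA {profile.bsa:.2f}",
            )

    set_spec = raw.get("settings", {}) or {}
    try:
        settings = EconSettings(
            discount_rate=float(set_spec.get("discount_rate", 0.03)),
            start_age=float(set_spec.get("start_age", 59.5)),
            horizon_age=float(set_spec.get("horizon_age", 100.0)),
            wtp_1x=float(set_spec.get("wtp_1x", 6100.0)),
            wtp_3x=float(set_spec.get("wtp_3x", 18300.0)),
            half_cycle_correction=bool(set_spec.get("half_cycle_correction", False)),
        )
    except ValueError as exc:
        raise ConfigError("settings", str(exc)) from None

    bg_spec = raw.get("background_mortality", {}) or {}
    lt_path = bg_spec.get("life_table")
    if lt_path:
        lt_file = Path(lt_path)
        if base_dir is not None and not lt_file.is_absolute():
            lt_file = base_dir / lt_file
        life_table = LifeTable.from_csv(lt_file)
    else:
        life_table = default_life_table()

    sens = raw.get("sensitivity", {}) or {}
    grid_spec = sens.get("wtp_grid", {}) or {}
    wtp_grid = np.arange(
        float(grid_spec.get("start", 0.0)),
        float(grid_spec.get("stop", 20000.0)) + 1e-9,
        float(grid_spec.get("step", 500.0)),
    )

    checks = []
    for i, c in enumerate(raw.get("validation", []) or []):
        here = f"validation[{i}]"
        checks.append(
            SurvivalCheck(
                strategy=str(_require(c, "strategy", here)),
                endpoint=str(_require(c, "endpoint", here)),
                years=float(_require(c, "years", here)),
                expected_pct=float(_require(c, "expected_pct", here)),
                trial_pct=(
                    float(c["trial_pct"]) if c.get("trial_pct") is not None else None
                ),
            )
        )

    try:
        return AnalysisConfig(
            base_rfs=base_rfs,
            base_os=base_os,
            strategies=tuple(strategies),
            reference=str(_require(raw, "reference", "")),
            intervention=str(raw.get("intervention", strategies[-1].name)),
            costs=costs,
            utilities=utilities,
            profile=profile,
            settings=settings,
            life_table=life_table,
            background_mode=str(bg_spec.get("mode", "additive")),
            background_from_week=float(bg_spec.get("from_week", 260.0)),
            death_attribution=str(costing.get("death_attribution", "excess")),
            followup_interval_weeks=float(
                costing.get("followup_interval_weeks", 12.0)
            ),
            psa_iterations=int(sens.get("psa_iterations", 1000)),
            seed=int(sens.get("seed", 20130101)),
            wtp_grid=wtp_grid,
            discount_range=tuple(sens.get("discount_range", (0.0, 0.06))),
            followup_interval_range=tuple(
                sens.get("followup_interval_range", (6.0, 26.0))
            ),
            validation=tuple(checks),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError("settings", str(exc)) from None


def default_config_path() -> Path:
    return DATA_DIR / "basecase.yaml"


def default_config() -> AnalysisConfig:
    """The shipped base case (published model inputs)."""
    return load_config(default_config_path())
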