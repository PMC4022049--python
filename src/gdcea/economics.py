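"""Lifetime outcomes, costs, ICERs and the deterministic scenario analyses.

A cohort trace is turned into three lifetime totals: years free of
end-organ damage (YFEOD: time in the asymptomatic, signs/symptoms and
recovery states), QALYs (occupancy-weighted EQ-5D utilities, one tariff at
a time, dead = 0), and costs in 2009 euros (hospital + out-of-hospital
+ ERT medication in ERT arms + optionally production loss during the
productive age window).  Effects and costs are discounted at different
rates (1.5% and 4% by Dutch convention); rewards accrue at cycle start, so
cycle k carries the factor (1+r)^-k and the first cycle is undiscounted.

``run_scenario`` reproduces the structure of the published scenario tables:
base case, production loss included, 25% ERT cost reduction, and the two
historical 1991-cohort scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort_engine import CohortTrace, run_cohort
from .params import (
    ALIVE_STATES,
    STATE_INDEX,
    STATE_ORDER,
    YFEOD_STATES,
    DiseaseState,
    LifeTable,
    ModelConfig,
    SchemaError,
    StrategySpec,
    UtilitySpec,
)

__all__ = [
    "DiscountSpec",
    "OutcomeSummary",
    "IncrementalResult",
    "ScenarioSpec",
    "ScenarioResult",
    "standard_scenarios",
    "discounted_sum",
    "yfeod_from_trace",
    "qalys_from_trace",
    "costs_from_trace",
    "icer",
    "run_scenario",
]

SCENARIO_NAMES = (
    "base",
    "production_loss",
    "ert_cost_reduction",
    "historical_I",
    "historical_II",
)


@dataclass(frozen=True)
class DiscountSpec:
    """Differential discounting of effects and costs."""

    rate_effects: float = 0.015
    rate_costs: float = 0.04
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rate_effects < 0 or self.rate_costs < 0:
            raise SchemaError("discount rates must be non-negative")

    @property
    def effective_rate_effects(self) -> float:
        return self.rate_effects if self.enabled else 0.0

    @property
    def effective_rate_costs(self) -> float:
        return self.rate_costs if self.enabled else 0.0


@dataclass(frozen=True)
class OutcomeSummary:
    """Lifetime totals for one strategy under one scenario."""

    strategy: str
    yfeod: float
    qalys: float
    costs: float
    discounted: bool
    scenario: str = "base"


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise differences and cost-effectiveness ratios (intervention minus comparator)."""

    delta_yfeod: float
    delta_qalys: float
    delta_costs: float
    icer_per_yfeod: "float | None"
    icer_per_qaly: "float | None"
    dominance: "str | None"  # "dominant" | "dominated" | None (QALY-based)


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic scenario of the analysis.

    ``ert_strategy`` selects which ERT parameter set faces ``no_ert``;
    ``start_distribution`` (when set) replaces the birth-cohort start in
    both arms, as in the historical 1991-cohort scenarios.
    """

    name: str
    ert_cost_multiplier: float = 1.0
    include_production_loss: bool = False
    start_distribution: "Mapping[DiseaseState, float] | None" = None
    ert_strategy: str = "ert_base"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ert_cost_multiplier <= 1.0:
            raise SchemaError("ERT cost multiplier must lie in [0, 1]")
        if self.name == "base":
            if (
                self.ert_cost_multiplier != 1.0
                or self.include_production_loss
                or self.start_distribution is not None
            ):
                raise SchemaError("the base scenario admits no overrides")


def standard_scenarios(config: ModelConfig) -> dict[str, ScenarioSpec]:
    """The five published scenarios; historical start distributions come
    from the run configuration."""
    scenarios = {
        "base": ScenarioSpec("base"),
        "production_loss": ScenarioSpec(
            "production_loss", include_production_loss=True
        ),
        "ert_cost_reduction": ScenarioSpec(
            "ert_cost_reduction", ert_cost_multiplier=0.75
        ),
    }
    for variant in ("historical_I", "historical_II"):
        dist = config.scenario_start_distributions.get(variant)
        if dist is not None:
            scenarios[variant] = ScenarioSpec(
                variant, start_distribution=dist, ert_strategy="ert_historical"
            )
    return scenarios


def discounted_sum(stream: Iterable[float], rate: float) -> float:
    """Present value of a per-cycle stream; cycle 0 is undiscounted."""
    if rate < 0:
        raise SchemaError(f"negative discount rate {rate}")
    stream = np.asarray(list(stream) if not isinstance(stream, np.ndarray) else stream,
                        dtype=float)
    if stream.size == 0:
        return 0.0
    factors = (1.0 + rate) ** -np.arange(stream.size)
    return float(stream @ factors)


def yfeod_from_trace(trace: CohortTrace, discount: DiscountSpec) -> float:
    """Lifetime years free of end-organ damage."""
    idx = [STATE_INDEX[s] for s in YFEOD_STATES]
    per_cycle = trace.occupancy[:, idx].sum(axis=1)
    return discounted_sum(per_cycle, discount.effective_rate_effects)


def _utility_vector(
    utilities: "Mapping[DiseaseState, float] | Iterable[UtilitySpec]",
    tariff: "str | None",
) -> np.ndarray:
    values: dict[DiseaseState, float] = {}
    if isinstance(utilities, Mapping):
        values = {DiseaseState(s): float(u) for s, u in utilities.items()}
    else:
        for spec in utilities:
            if tariff is None or spec.tariff == tariff:
                values[spec.state] = spec.mean_u
    vec = np.zeros(len(STATE_ORDER))
    for state in ALIVE_STATES:
        if state not in values:
            raise SchemaError(f"missing utility for alive state {state}")
        vec[STATE_INDEX[state]] = values[state]
    vec[STATE_INDEX[DiseaseState.DEAD]] = 0.0  # by convention, not configurable
    return vec


def qalys_from_trace(
    trace: CohortTrace,
    utilities: "Mapping[DiseaseState, float] | Iterable[UtilitySpec]",
    discount: DiscountSpec,
    tariff: "str | None" = None,
) -> float:
    """Lifetime QALYs: occupancy-weighted state utilities per cycle."""
    vec = _utility_vector(utilities, tariff)
    per_cycle = trace.occupancy @ vec
    return discounted_sum(per_cycle, discount.effective_rate_effects)


def costs_from_trace(
    trace: CohortTrace,
    strategy: StrategySpec,
    scenario: ScenarioSpec,
    discount: DiscountSpec,
    productive_age_window: tuple[int, int] = (25, 64),
) -> float:
    """Lifetime costs (2009 euros) of a trace under one scenario.

    ERT medication costs accrue only in ERT arms and never in the
    asymptomatic state; production loss enters only when the scenario
    activates it and only for cycles within the productive age window.
    """
    n_states = len(STATE_ORDER)
    medical = np.zeros(n_states)
    production = np.zeros(n_states)
    multiplier = strategy.ert_cost_multiplier * scenario.ert_cost_multiplier
    for state in ALIVE_STATES:
        i = STATE_INDEX[state]
        medical[i] = strategy.cost(state, "hospital") + strategy.cost(
            state, "out_of_hospital"
        )
        if strategy.is_ert and state is not DiseaseState.ASYMPTOMATIC:
            medical[i] += strategy.cost(state, "ert") * multiplier
        production[i] = strategy.cost(state, "production_loss")
    per_cycle = trace.occupancy @ medical
    if scenario.include_production_loss:
        ages = np.arange(trace.n_cycles)
        lo, hi = productive_age_window
        window = (ages >= lo) & (ages <= hi)
        per_cycle = per_cycle + window * (trace.occupancy @ production)
    return discounted_sum(per_cycle, discount.effective_rate_costs)


def icer(intervention: OutcomeSummary, comparator: OutcomeSummary) -> IncrementalResult:
    """Incremental result of an intervention against a comparator."""
    if intervention.discounted != comparator.discounted:
        raise SchemaError("cannot compare discounted with undiscounted outcomes")
    if intervention.scenario != comparator.scenario:
        raise SchemaError("cannot compare outcomes across scenarios")
    d_yfeod = intervention.yfeod - comparator.yfeod
    d_qaly = intervention.qalys - comparator.qalys
    d_cost = intervention.costs - comparator.costs
    ratio_yfeod = d_cost / d_yfeod if d_yfeod != 0 else None
    ratio_qaly = d_cost / d_qaly if d_qaly != 0 else None
    dominance = None
    if d_qaly > 0 and d_cost < 0:
        dominance = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "dominated"
    return IncrementalResult(
        delta_yfeod=d_yfeod,
        delta_qalys=d_qaly,
        delta_costs=d_cost,
        icer_per_yfeod=ratio_yfeod,
        icer_per_qaly=ratio_qaly,
        dominance=dominance,
    )


@dataclass
class ScenarioResult:
    """Per-arm lifetime outcomes and incremental results, discounted and not."""

    scenario: ScenarioSpec
    outcomes: dict[tuple[str, bool], OutcomeSummary]
    incremental: dict[bool, IncrementalResult]
    traces: dict[str, CohortTrace] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for discounted in (False, True):
            inc = self.incremental[discounted]
            arms = {
                arm: s
                for (arm, d), s in self.outcomes.items()
                if d is discounted
            }
            ert_arm = next(a for a in arms if a != "no_ert")
            rows.append(
                {
                    "scenario": self.scenario.name,
                    "discounted": discounted,
                    "yfeod_ert": arms[ert_arm].yfeod,
                    "yfeod_no_ert": arms["no_ert"].yfeod,
                    "delta_yfeod": inc.delta_yfeod,
                    "qalys_ert": arms[ert_arm].qalys,
                    "qalys_no_ert": arms["no_ert"].qalys,
                    "delta_qalys": inc.delta_qalys,
                    "costs_ert": arms[ert_arm].costs,
                    "costs_no_ert": arms["no_ert"].costs,
                    "delta_costs": inc.delta_costs,
                    "icer_per_yfeod": inc.icer_per_yfeod,
                    "icer_per_qaly": inc.icer_per_qaly,
                }
            )
        return pd.DataFrame(rows)


def run_scenario(
    scenario: ScenarioSpec,
    strategies: Mapping[str, StrategySpec],
    config: ModelConfig,
    life_table: LifeTable,
    tariff: "str | None" = None,
) -> ScenarioResult:
    """Evaluate one scenario: both arms, discounted and undiscounted."""
    tariff = tariff or config.tariff
    if scenario.name.startswith("historical") and scenario.start_distribution is None:
        raise SchemaError(
            f"scenario {scenario.name} requires a start distribution"
        )
    arm_labels = ("no_ert", scenario.ert_strategy)
    start = None
    if scenario.start_distribution is not None:
        vec = np.zeros(len(STATE_ORDER))
        for state, frac in scenario.start_distribution.items():
            vec[STATE_INDEX[DiseaseState(state)]] = frac
        if abs(vec.sum() - 1.0) > 1e-9:
            raise SchemaError("scenario start distribution must sum to 1")
        start = vec
    outcomes: dict[tuple[str, bool], OutcomeSummary] = {}
    traces: dict[str, CohortTrace] = {}
    for label in arm_labels:
        if label not in strategies:
            raise SchemaError(f"strategy {label!r} not available")
        strat = strategies[label]
        trace = run_cohort(strat, config, life_table, start_distribution=start)
        traces[label] = trace
        for discounted in (False, True):
            disc = DiscountSpec(
                config.discount_effects, config.discount_costs, enabled=discounted
            )
            outcomes[(label, discounted)] = OutcomeSummary(
                strategy=label,
                yfeod=yfeod_from_trace(trace, disc),
                qalys=qalys_from_trace(trace, strat.utilities, disc, tariff),
                costs=costs_from_trace(
                    trace, strat, scenario, disc, config.productive_age_window
                ),
                discounted=discounted,
                scenario=scenario.name,
            )
    incremental = {
        discounted: icer(
            outcomes[(scenario.ert_strategy, discounted)],
            outcomes[("no_ert", discounted)],
        )
        for discounted in (False, True)
    }
    return ScenarioResult(scenario, outcomes, incremental, traces)
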