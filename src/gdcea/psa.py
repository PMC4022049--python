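"""Probabilistic sensitivity analysis.

Second-order parameter uncertainty is propagated by drawing annual
transition probabilities from their beta distributions (and, in
``all_parameters`` mode, state utilities and annual costs from triangular
distributions whose mode is the mean estimate and whose range is the 95%
confidence interval).  Each draw is evaluated either as a deterministic
cohort (fast; second-order uncertainty only) or as a first-order
microsimulation of ``psa_trials`` individual patients per arm, with common
random numbers across arms within a draw.  Within a draw the same sampled
utility and cost tables apply to both arms (treated and untreated patients
share state values).

Outputs are the per-draw incremental cost/effect pairs (the
cost-effectiveness plane), quadrant shares, and the cost-effectiveness
acceptability curve via the net-monetary-benefit rule NMB = lambda*dE - dC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .cohort_engine import run_cohort, run_microsimulation, trace_from_trajectories
from .economics import (
    DiscountSpec,
    ScenarioSpec,
    costs_from_trace,
    qalys_from_trace,
    yfeod_from_trace,
)
from .params import (
    LifeTable,
    ModelConfig,
    SchemaError,
    StrategySpec,
    UtilitySpec,
    CostSpec,
    sample_triangular,
)

__all__ = [
    "PsaResult",
    "CeacCurve",
    "WtpReadout",
    "sample_parameters",
    "run_psa",
    "quadrant_shares",
    "ceac",
    "wtp_at_probability",
    "plot_ce_plane",
    "plot_ceac",
]

MODES = ("transitions_only", "all_parameters")


@dataclass
class PsaResult:
    """Per-draw incremental outcomes (ERT arm minus no-ERT arm)."""

    draws: pd.DataFrame  # columns: draw, delta_cost, delta_qaly, delta_yfeod
    mode: str
    discounted: bool
    evaluation: str  # "cohort" | "microsim"
    seed: "int | None" = None

    @property
    def n_draws(self) -> int:
        return len(self.draws)


@dataclass
class CeacCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.wtp = np.asarray(self.wtp, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.wtp.shape != self.probability.shape:
            raise SchemaError("WTP grid and probabilities must align")
        if np.any(np.diff(self.wtp) <= 0):
            raise SchemaError("WTP grid must be strictly increasing")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise SchemaError("probabilities must lie in [0, 1]")


def _sample_transitions(
    strategy: StrategySpec, rng: np.random.Generator
) -> StrategySpec:
    sampled = []
    for tr in strategy.transitions:
        if tr.alpha is None:
            sampled.append(tr)  # degenerate: no distribution fitted
        else:
            p = float(rng.beta(tr.alpha, tr.beta))
            sampled.append(replace(tr, mean_p=p, alpha=None, beta=None))
    return replace(strategy, transitions=tuple(sampled))


def _sample_utility_table(
    utilities: tuple[UtilitySpec, ...], rng: np.random.Generator
) -> tuple[UtilitySpec, ...]:
    out = []
    for u in utilities:
        if u.lcl is None:
            out.append(u)  # no interval printed: kept fixed at the mean
        else:
            draw = sample_triangular(u.mean_u, u.lcl, u.ucl, rng)
            out.append(replace(u, mean_u=float(draw), lcl=None, ucl=None))
    return tuple(out)


def _sample_cost_table(
    costs: tuple[CostSpec, ...], rng: np.random.Generator
) -> tuple[CostSpec, ...]:
    out = []
    for c in costs:
        if c.lcl is None or c.lcl == c.ucl == c.mean_annual_cost:
            out.append(c)
        else:
            draw = sample_triangular(c.mean_annual_cost, c.lcl, c.ucl, rng)
            out.append(replace(c, mean_annual_cost=float(max(draw, 0.0)),
                               lcl=None, ucl=None))
    return tuple(out)


def sample_parameters(
    strategies: Mapping[str, StrategySpec],
    mode: str,
    rng: np.random.Generator,
) -> dict[str, StrategySpec]:
    """One second-order draw of every strategy's parameter set.

    Transition probabilities are drawn per strategy from their beta
    distributions.  In ``all_parameters`` mode one utility table and one
    cost table are drawn (triangular) and shared by all

    arms, reflecting the assumption that treated and untreated patients in
    the same state have the same utilities and non-ERT costs.  Parameters
    without a printed interval are degenerate and stay at their mean.
    """
    if mode not in MODES:
        raise SchemaError(f"unknown PSA mode {mode!r}; expected one of {MODES}")
    sampled = {label: _sample_transitions(s, rng) for label, s in strategies.items()}
    if mode == "all_parameters":
        reference = next(
            (s for s in strategies.values() if s.is_ert),
            next(iter(strategies.values())),
        )
        utility_table = _sample_utility_table(reference.utilities, rng)
        cost_table = _sample_cost_table(reference.costs, rng)
        for label, strat in sampled.items():
            costs = cost_table
            if not strat.is_ert:
                costs = tuple(
                    replace(c, mean_annual_cost=0.0) if c.component == "ert" else c
                    for c in cost_table
                )
            sampled[label] = replace(strat, utilities=utility_table, costs=costs)
    return sampled


def _evaluate_arm(
    strategy: StrategySpec,
    config: ModelConfig,
    life_table: LifeTable,
    scenario: ScenarioSpec,
    discount: DiscountSpec,
    evaluation: str,
    n_trials: int,
    arm_rng: "np.random.Generator | None",
) -> tuple[float, float, float]:
    if evaluation == "cohort":
        trace = run_cohort(strategy, config, life_table)
    elif evaluation == "microsim":
        traj = run_microsimulation(
            strategy, config, life_table, n_trials, arm_rng
        )
        trace = trace_from_trajectories(traj)
    else:
        raise SchemaError(f"unknown evaluation mode {evaluation!r}")
    return (
        costs_from_trace(trace, strategy, scenario, discount,
                         config.productive_age_window),
        qalys_from_trace(trace, strategy.utilities, discount, config.tariff),
        yfeod_from_trace(trace, discount),
    )


def run_psa(
    strategies: Mapping[str, StrategySpec],
    config: ModelConfig,
    life_table: LifeTable,
    mode: str = "transitions_only",
    rng: "np.random.Generator | None" = None,
    evaluation: str = "microsim",
    discounted: bool = False,
    ert_arm: str = "ert_base",
    common_random_numbers: bool = True,
) -> PsaResult:
    """Monte Carlo simulation: ``config.psa_draws`` second-order draws, each
    evaluated on both arms (with ``config.psa_trials`` first-order trials in
    microsimulation mode) under the base-case scenario."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scenario = ScenarioSpec("base")
    discount = DiscountSpec(
        config.discount_effects, config.discount_costs, enabled=discounted
    )
    arms = ("no_ert", ert_arm)
    for arm in arms:
        if arm not in strategies:
            raise SchemaError(f"strategy {arm!r} not available")
    records = []
    for d in range(config.psa_draws):
        sampled = sample_parameters(strategies, mode, rng)
        trial_seed = int(rng.integers(0, 2**31 - 1))
        values = {}
        for j, arm in enumerate(arms):
            arm_seed = trial_seed if common_random_numbers else trial_seed + j + 1
            arm_rng = (
                np.random.default_rng(arm_seed) if evaluation == "microsim" else None
            )
            values[arm] = _evaluate_arm(
                sampled[arm], config, life_table, scenario, discount,
                evaluation, config.psa_trials, arm_rng,
            )
        records.append(
            {
                "draw": d,
                "delta_cost": values[ert_arm][0] - values["no_ert"][0],
                "delta_qaly": values[ert_arm][1] - values["no_ert"][1],
                "delta_yfeod": values[ert_arm][2] - values["no_ert"][2],
            }
        )
    return PsaResult(
        draws=pd.DataFrame(records),
        mode=mode,
        discounted=discounted,
        evaluation=evaluation,
        seed=config.seed,
    )


def quadrant_shares(result: PsaResult) -> dict[str, float]:
    """Fractions of draws per cost-effectiveness-plane quadrant.

    The x-axis is the QALY difference, the y-axis the cost difference;
    boundary points count toward the positive side.
    """
    if result.n_draws == 0:
        raise SchemaError("empty PSA result")
    de = result.draws["delta_qaly"].to_numpy()
    dc = result.draws["delta_cost"].to_numpy()
    n = de.size
    return {
        "upper_right": float(np.sum((de >= 0) & (dc >= 0)) / n),
        "upper_left": float(np.sum((de < 0) & (dc >= 0)) / n),
        "lower_right": float(np.sum((de >= 0) & (dc < 0)) / n),
        "lower_left": float(np.sum((de < 0) & (dc < 0)) / n),
    }


def ceac(
    result: PsaResult,
    wtp_grid: np.ndarray,
    effect: str = "delta_qaly",
) -> CeacCurve:
    """Probability that ERT is cost-effective: fraction of draws with
    positive net monetary benefit lambda*dE - dC at each WTP value."""
    if result.n_draws == 0:
        raise SchemaError("empty PSA result")
    if effect not in ("delta_qaly", "delta_yfeod"):
        raise SchemaError(f"unknown effect column {effect!r}")
    de = result.draws[effect].to_numpy()
    dc = result.draws["delta_cost"].to_numpy()
    wtp = np.asarray(wtp_grid, dtype=float)
    nmb = wtp[:, None] * de[None, :] - dc[None, :]
    return CeacCurve(wtp, (nmb > 0).mean(axis=1))


class WtpReadout(NamedTuple):
    """WTP at which the acceptability curve first reaches a probability."""

    wtp: float
    at_boundary: bool


def wtp_at_probability(curve: CeacCurve, q: float) -> WtpReadout:
    """Smallest WTP where the CEAC reaches probability ``q``, linearly
    interpolated between grid points; the grid boundary is returned with a
    flag when the curve never spans ``q``."""
    if not 0.0 <= q <= 1.0:
        raise SchemaError(f"probability {q} outside [0, 1]")
    p = curve.probability
    above = np.nonzero(p >= q)[0]
    if above.size == 0:
        return WtpReadout(float(curve.wtp[-1]), True)
    j = int(above[0])
    if j == 0:
        # already cost-effective with probability >= q at the grid start
        return WtpReadout(float(curve.wtp[0]), True)
    lo_p, hi_p = p[j - 1], p[j]
    lo_w, hi_w = curve.wtp[j - 1], curve.wtp[j]
    if hi_p == lo_p:
        return WtpReadout(float(hi_w), False)
    frac = (q - lo_p) / (hi_p - lo_p)
    return WtpReadout(float(lo_w + frac * (hi_w - lo_w)), False)


def plot_ce_plane(result: PsaResult, path) -> None:
    """Scatter of incremental costs against incremental QALYs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.draws["delta_qaly"], result.draws["delta_cost"], s=8, alpha=0.5)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental costs (2009 euros)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, path) -> None:
    """Cost-effectiveness acceptability curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability)
    ax.set_xlabel("Willingness to pay (euros per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
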