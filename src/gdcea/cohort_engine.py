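"""Discrete-time Markov engine: cohort traces and individual microsimulation.

The model runs on one-year cycles from birth (age 0) to the horizon.  For
each cycle an 8x8 row-stochastic transition matrix is built from the
strategy's annual disease-transition probabilities and the background
life table.  Within a cycle, survival is evaluated first: the probability
of dying equals the age-specific background probability q(age) (plus the
malignancy excess in the malignancy state, capped at 1), and disease
transitions apply conditional on surviving the cycle.  No half-cycle
correction is applied; state membership and rewards are read at cycle
start.

Two evaluation modes share the same matrices: the deterministic closed
cohort (repeated vector-matrix products, ``run_cohort``) and seeded
individual microsimulation (``run_microsimulation``) used for first-order
trials in the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    ALIVE_STATES,
    STATE_INDEX,
    STATE_ORDER,
    DiseaseState,
    LifeTable,
    ModelConfig,
    SchemaError,
    StrategySpec,
)

__all__ = [
    "CohortTrace",
    "PatientTrajectories",
    "build_matrix",
    "build_matrix_sequence",
    "run_cohort",
    "run_microsimulation",
    "trace_from_trajectories",
]

_DEAD = STATE_INDEX[DiseaseState.DEAD]
_N = len(STATE_ORDER)


@dataclass
class CohortTrace:
    """Start-of-cycle occupancy fractions of a closed cohort.

    Row k holds the state distribution at the start of cycle k (age k);
    there are ``horizon`` rows.
    """

    occupancy: np.ndarray
    start_distribution: np.ndarray
    strategy_label: str

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != _N:
            raise SchemaError(f"occupancy must be (cycles, {_N})")
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-10):
            worst = int(np.argmax(np.abs(sums - 1.0)))
            raise SchemaError(
                f"occupancy at cycle {worst} sums to {sums[worst]!r}, not 1"
            )
        dead = self.occupancy[:, _DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise SchemaError("dead-state occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def state_occupancy(self, state: DiseaseState) -> np.ndarray:
        return self.occupancy[:, STATE_INDEX[state]]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.occupancy, columns=[s.value for s in STATE_ORDER]
        )
        frame.insert(0, "cycle", np.arange(self.n_cycles))
        frame.insert(1, "age", np.arange(self.n_cycles))
        frame["row_sum"] = self.occupancy.sum(axis=1)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PatientTrajectories:
    """State paths of simulated individuals; row i is one patient's
    start-of-cycle state index over the horizon."""

    states: np.ndarray
    strategy_label: str
    seed: "int | None" = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise SchemaError("trajectories must be a (patients, cycles) array")

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.states.shape[1]


def build_matrix(
    age: int, strategy: StrategySpec, life_table: LifeTable
) -> np.ndarray:
    """One-cycle transition matrix at a given age (survival first)."""
    q = life_table.annual_death_probability(age)
    matrix = np.zeros((_N, _N))
    matrix[_DEAD, _DEAD] = 1.0
    for state in ALIVE_STATES:
        i = STATE_INDEX[state]
        death = q
        if state is DiseaseState.MALIGNANCY:
            death = min(1.0, q + strategy.malignancy_excess_mortality)
        moves = strategy.outgoing(state)
        total = sum(moves.values())
        if total > 1.0:
            warnings.warn(
                f"outgoing probabilities from {state} sum to {total:.4f}; "
                "rescaling proportionally",
                stacklevel=2,
            )
            moves = {t: p / total for t, p in moves.items()}
            total = 1.0
        survive = 1.0 - death
        matrix[i, _DEAD] = death
        for target, p in moves.items():
            matrix[i, STATE_INDEX[target]] += p * survive
        matrix[i, i] += survive * (1.0 - total)
    return matrix


def build_matrix_sequence(
    strategy: StrategySpec, horizon_years: int, life_table: LifeTable
) -> np.ndarray:
    """Stack of per-cycle matrices for ages 0..horizon-1, shape (H, 8, 8)."""
    if horizon_years - 1 > life_table.max_age:
        raise SchemaError(
            f"life table ends at age {life_table.max_age}, "
            f"horizon needs {horizon_years - 1}"
        )
    return np.stack(
        [build_matrix(age, strategy, life_table) for age in range(horizon_years)]
    )


def run_cohort(
    strategy: StrategySpec,
    config: ModelConfig,
    life_table: LifeTable,
    start_distribution: "np.ndarray | None" = None,
) -> CohortTrace:
    """Deterministic closed-cohort trace over the configured horizon."""
    matrices = build_matrix_sequence(strategy, config.horizon_years, life_table)
    start = (
        strategy.start_vector()
        if start_distribution is None
        else np.asarray(start_distribution, dtype=float)
    )
    occupancy = np.empty((config.horizon_years, _N))
    occupancy[0] = start
    for k in range(config.horizon_years - 1):
        occupancy[k + 1] = occupancy[k] @ matrices[k]
    return CohortTrace(occupancy, start, strategy.label)


def run_microsimulation(
    strategy: StrategySpec,
    config: ModelConfig,
    life_table: LifeTable,
    n_patients: int,
    rng: np.random.Generator,
    start_distribution: "np.ndarray | None" = None,
) -> PatientTrajectories:
    """Simulate individual state paths from the same per-age matrices."""
    if n_patients < 1:
        raise SchemaError("need at least one simulated patient")
    matrices = build_matrix_sequence(strategy, config.horizon_years, life_table)
    cumulative = np.cumsum(matrices, axis=2)
    start = (
        strategy.start_vector()
        if start_distribution is None
        else np.asarray(start_distribution, dtype=float)
    )
    states = np.empty((n_patients, config.horizon_years), dtype=np.int8)
    states[:, 0] = rng.choice(_N, size=n_patients, p=start / start.sum())
    for k in range(config.horizon_years - 1):
        row_cum = cumulative[k][states[:, k]]
        u = rng.random(n_patients)
        nxt = (row_cum < u[:, None]).sum(axis=1)
        states[:, k + 1] = np.minimum(nxt, _N - 1)  # guard cumsum rounding
    return PatientTrajectories(states, strategy.label)


def trace_from_trajectories(trajectories: PatientTrajectories) -> CohortTrace:
    """Empirical occupancy fractions from simulated trajectories."""
    if trajectories.n_patients == 0:
        raise SchemaError("cannot build a trace from zero trajectories")
    counts = np.stack(
        [
            np.bincount(trajectories.states[:, k], minlength=_N)
            for k in range(trajectories.n_cycles)
        ]
    )
    occupancy = counts / trajectories.n_patients
    return CohortTrace(
        occupancy, occupancy[0].copy(), trajectories.strategy_label
    )
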