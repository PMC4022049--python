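"""Synthetic patient-level registry generator.

Emulates the structure of the Dutch Gaucher registry that calibration
expects — state episodes, quarterly EQ-5D observations, ERT dose episodes,
hospital procedure logs, quarterly out-of-hospital care and work/sick-leave
records — from a known ground-truth ``StrategySpec``, so that every
pipeline stage (calibration, cohort engine, economics, PSA) can be tested
end to end without any real or downloaded data.

Trajectories are drawn from the truth transition probabilities with the
same life-table mortality mechanism the cohort engine uses, at the model's
annual resolution; censoring is administrative at the follow-up horizon
plus uniform whole-year random censoring for a configurable fraction of
patients.  Utility observations add truncated (clipped-to-scale) normal
noise around the truth state means; dose records vary log-normally across
patients and switch dose within long episodes to exercise the
episode-length weighting of the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .calibration import (
    CENSORED,
    DEATH,
    TRANSITION_PREFIX,
    CalibrationResult,
    Registry,
)
from .cohort_engine import run_microsimulation
from .params import (
    ALIVE_STATES,
    MIN_UTILITY,
    STATE_INDEX,
    STATE_ORDER,
    DiseaseState,
    LifeTable,
    ModelConfig,
    SchemaError,
    StrategySpec,
    default_fixture_dir,
)

__all__ = [
    "SyntheticCohortSpec",
    "simulate_registry",
    "truth_report",
    "make_synthetic_life_table",
]

_DEAD = STATE_INDEX[DiseaseState.DEAD]


def make_synthetic_life_table(max_age: int = 85) -> LifeTable:
    """Gompertz-Makeham life table shaped like Dutch all-cause mortality
    around 2009 (synthetic stand-in; no national table is bundled)."""
    ages = np.arange(0, max_age + 1)
    q = 1.5e-4 + 2.2e-5 * np.exp(0.097 * ages)
    q[0] = 0.004
    return LifeTable(np.clip(q, 0.0, 1.0))


def _default_life_table() -> LifeTable:
    path = default_fixture_dir() / "life_table_synthetic.csv"
    if path.exists():
        return LifeTable.from_csv(path)
    return make_synthetic_life_table()


@dataclass
class SyntheticCohortSpec:
    """Ground truth and observation design of a synthetic registry.

    ``follow_up_years`` is the administrative censoring horizon from birth;
    ``censoring_rate`` is the fraction of patients additionally censored at
    a uniform whole year before that.  ``eq5d_observation_rate`` is the
    probability that any given quarter yields an EQ-5D questionnaire (and
    an out-of-hospital care report).
    """

    n_patients: int
    truth: StrategySpec
    life_table: "LifeTable | None" = None
    follow_up_years: int = 60
    eq5d_noise_sd: float = 0.05
    eq5d_observation_rate: float = 0.25
    dose_dispersion_sd: float = 0.2
    dose_switch_sd: float = 0.1
    employed_prob: float = 0.6
    disabled_prob: float = 0.15
    hours_per_workday: float = 8.0
    workdays_per_week: float = 5.0
    hourly_production_cost: float = 30.0
    outpatient_unit_cost: float = 60.0
    procedures_per_year: float = 4.0
    censoring_rate: float = 0.1
    tariff: str = "UK"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise SchemaError("n_patients must be non-negative")
        if self.eq5d_noise_sd < 0 or self.dose_dispersion_sd < 0:
            raise SchemaError("dispersions must be non-negative")
        for rate in (self.eq5d_observation_rate, self.censoring_rate,
                     self.employed_prob, self.disabled_prob):
            if not 0.0 <= rate <= 1.0:
                raise SchemaError("rates and probabilities must lie in [0, 1]")
        if self.follow_up_years < 2:
            raise SchemaError("follow-up must span at least two years")
        if self.life_table is None:
            self.life_table = _default_life_table()


def _episodes_from_paths(
    states: np.ndarray, horizons: np.ndarray
) -> pd.DataFrame:
    """Run-length-encode state paths into episode records.

    ``horizons[i]`` is the last observed time of patient i; transitions at
    exactly that time are observed (events precede censorings).
    """
    rows: list[tuple] = []
    for pid in range(states.shape[0]):
        h = int(horizons[pid])
        path = states[pid, : h + 1]
        start = 0
        for k in range(1, h + 1):
            if path[k] != path[start]:
                state = STATE_ORDER[path[start]]
                if state is not DiseaseState.DEAD:
                    new = STATE_ORDER[path[k]]
                    event = (
                        DEATH
                        if new is DiseaseState.DEAD
                        else TRANSITION_PREFIX + new.value
                    )
                    rows.append((pid, state.value, float(start), float(k), event))
                start = k
        state = STATE_ORDER[path[start]]
        if state is not DiseaseState.DEAD:
            rows.append((pid, state.value, float(start), float(h), CENSORED))
    return pd.DataFrame(
        rows, columns=["patient_id", "state", "start_age", "end_age", "end_event"]
    )


def _work_profile(
    spec: SyntheticCohortSpec, state: DiseaseState
) -> tuple[float, float, float]:
    """(employed_prob, disabled_prob, mean sick days/fortnight) chosen so the
    expected human-capital loss approximates the truth cost for the state."""
    target = spec.truth.cost(state, "production_loss")
    if target <= 0:
        return spec.employed_prob, 0.0, 0.0
    h, w, r = spec.hours_per_workday, spec.workdays_per_week, spec.hourly_production_cost
    disabled_part = spec.disabled_prob * 52.0 * w * h * r
    denom = spec.employed_prob * 26.0 * h * r
    sick = (target - disabled_part) / denom if denom > 0 else 0.0
    return spec.employed_prob, spec.disabled_prob, float(np.clip(sick, 0.0, 12.0))


def simulate_registry(
    spec: SyntheticCohortSpec,
) -> tuple[Registry, CalibrationResult]:
    """Generate all registry record sets plus a truth echo.

    Returns the registry and ``truth_report(spec)`` so recovery can be
    compared field by field.
    """
    if spec.n_patients == 0:
        return Registry.empty(), truth_report(spec)
    rng = np.random.default_rng(spec.seed)
    follow_up = spec.follow_up_years
    config = ModelConfig(horizon_years=follow_up, seed=spec.seed)
    traj = run_microsimulation(
        spec.truth, config, spec.life_table, spec.n_patients, rng
    )
    states = traj.states  # (n, follow_up), cycle k = age k

    horizons = np.full(spec.n_patients, follow_up - 1)
    censored = rng.random(spec.n_patients) < spec.censoring_rate
    horizons[censored] = rng.integers(1, follow_up - 1, size=censored.sum())

    episodes = _episodes_from_paths(states, horizons)

    # alive patient-cycles inside the observation window
    cycle_grid = np.arange(follow_up)
    observed = cycle_grid[None, :] < horizons[:, None]
    alive = (states != _DEAD) & observed
    pid_idx, cyc_idx = np.nonzero(alive)
    st_idx = states[pid_idx, cyc_idx]

    truth_u = np.array(
        [
            spec.truth.utility(s, spec.tariff) if s is not DiseaseState.DEAD else 0.0
            for s in STATE_ORDER
        ]
    )
    truth_hospital = np.array(
        [
            spec.truth.cost(s, "hospital") if s is not DiseaseState.DEAD else 0.0
            for s in STATE_ORDER
        ]
    )
    truth_outpatient = np.array(
        [
            spec.truth.cost(s, "out_of_hospital") if s is not DiseaseState.DEAD else 0.0
            for s in STATE_ORDER
        ]
    )

    # quarterly EQ-5D observations with clipped normal noise
    eq_rows = []
    out_rows = []
    for quarter in range(4):
        seen = rng.random(pid_idx.size) < spec.eq5d_observation_rate
        if not np.any(seen):
            continue
        u = truth_u[st_idx[seen]] + rng.normal(0.0, spec.eq5d_noise_sd, seen.sum())
        eq_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid_idx[seen],
                    "age": cyc_idx[seen] + quarter / 4.0,
                    "state": [STATE_ORDER[s].value for s in st_idx[seen]],
                    "utility": np.clip(u, MIN_UTILITY, 1.0),
                    "tariff": spec.tariff,
                }
            )
        )
        rate = truth_outpatient[st_idx[seen]] / (4.0 * spec.outpatient_unit_cost)
        out_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid_idx[seen],
                    "state": [STATE_ORDER[s].value for s in st_idx[seen]],
                    "quarter_age": cyc_idx[seen] + quarter / 4.0,
                    "visits": rng.poisson(rate),
                    "unit_cost": spec.outpatient_unit_cost,
                }
            )
        )
    eq5d = (
        pd.concat(eq_rows, ignore_index=True)
        if eq_rows
        else pd.DataFrame(columns=["patient_id", "age", "state", "utility", "tariff"])
    )
    outpatient = (
        pd.concat(out_rows, ignore_index=True)
        if out_rows
        else pd.DataFrame(
            columns=["patient_id", "state", "quarter_age", "visits", "unit_cost"]
        )
    )

    # yearly procedure logs: Poisson counts at a per-state unit cost that
    # reproduces the truth annual hospital cost in expectation
    unit = truth_hospital / spec.procedures_per_year
    counts = rng.poisson(spec.procedures_per_year, pid_idx.size)
    procedures = pd.DataFrame(
        {
            "patient_id": pid_idx,
            "age": cyc_idx + 0.5,
            "state": [STATE_ORDER[s].value for s in st_idx],
            "unit_cost": unit[st_idx],
            "count": counts,
        }
    )

    # ERT dose episodes from state episodes (ERT arms, symptomatic states)
    dose_rows: list[tuple] = []
    if spec.truth.is_ert:
        factors = np.exp(
            rng.normal(
                -0.5 * spec.dose_dispersion_sd**2,
                spec.dose_dispersion_sd,
                spec.n_patients,
            )
        )
        ert_states = {
            s.value: spec.truth.ert_dosing.get(s, 0.0)
            for s in ALIVE_STATES
            if s is not DiseaseState.ASYMPTOMATIC
        }
        for row in episodes.itertuples(index=False):
            yearly_vials = ert_states.get(row.state, 0.0)
            if yearly_vials <= 0:
                continue
            length = row.end_age - row.start_age
            if length <= 0:
                continue
            base = yearly_vials / 12.0 * factors[int(row.patient_id)]
            pieces: list[tuple[float, float]]
            if length >= 2:
                mid = row.start_age + length / 2.0
                pieces = [(row.start_age, mid), (mid, row.end_age)]
            else:
                pieces = [(row.start_age, row.end_age)]
            for lo, hi in pieces:
                switch = np.exp(
                    rng.normal(-0.5 * spec.dose_switch_sd**2, spec.dose_switch_sd)
                )
                dose_rows.append(
                    (int(row.patient_id), row.state, lo, hi, base * switch)
                )
    doses = pd.DataFrame(
        dose_rows,
        columns=[
            "patient_id",
            "state",
            "episode_start_age",
            "episode_end_age",
            "vials_per_month",
        ],
    )

    # one work record per patient per visited state
    seen_states = (
        pd.DataFrame({"patient_id": pid_idx, "state": st_idx})
        .drop_duplicates()
        .reset_index(drop=True)
    )
    work_rows = []
    for state_idx, grp in seen_states.groupby("state"):
        state = STATE_ORDER[int(state_idx)]
        employed_p, disabled_p, sick_mean = _work_profile(spec, state)
        m = len(grp)
        u = rng.random(m)
        disabled = u < disabled_p
        employed = (~disabled) & (u < disabled_p + employed_p)
        sick = np.zeros(m)
        if sick_mean > 0:
            sick = np.minimum(rng.exponential(sick_mean, m), 14.0)
        sick = np.where(employed, sick, 0.0)
        work_rows.append(
            pd.DataFrame(
                {
                    "patient_id": grp["patient_id"].to_numpy(),
                    "state": state.value,
                    "employed": employed,
                    "disabled_due_to_gd": disabled,
                    "hours_per_workday": spec.hours_per_workday,
                    "workdays_per_week": spec.workdays_per_week,
                    "sick_days_per_fortnight": sick,
                }
            )
        )
    work = (
        pd.concat(work_rows, ignore_index=True)
        if work_rows
        else pd.DataFrame(columns=list(Registry.empty().work.columns))
    )

    registry = Registry(
        episodes=episodes,
        eq5d=eq5d,
        doses=doses,
        procedures=procedures,
        outpatient=outpatient,
        work=work,
    )
    return registry, truth_report(spec)


def truth_report(spec: SyntheticCohortSpec) -> CalibrationResult:
    """Ground-truth parameters in the schema calibration emits."""
    utilities = tuple(
        u for u in spec.truth.utilities if u.tariff == spec.tariff
    )
    return CalibrationResult(
        transitions=spec.truth.transitions,
        utilities=utilities,
        costs=spec.truth.costs,
        ert_dosing=dict(spec.truth.ert_dosing),
        diagnostics=pd.DataFrame(
            [{"estimate": "truth", "n": spec.n_patients}]
        ),
        missing=(),
    )
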