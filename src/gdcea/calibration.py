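"""Registry-to-parameter calibration.

Turns patient-level registry records into the quantities the Markov model
consumes, following the study's estimation procedures:

* time from one disease state to the next by Kaplan-Meier analysis with a
  competing-risk correction (cause-specific-hazard cumulative incidence,
  Aalen-Johansen form), read off either where half the state's cohort has
  reached the destination (median-time rule) or, failing that, at the last
  point with at least four patients still at risk;
* conversion of the cumulative proportion into a constant annual
  probability via the Markov correction factor p = 1 - (1 - P)^(1/t);
* two-stage EQ-5D utility averaging (per patient per state, then over
  patients) with bias-corrected and accelerated bootstrap CIs resampling
  patients;
* per-state annual ERT vial consumption (episode-length-weighted), hospital
  procedure costs per year of follow-up, quarterly out-of-hospital costs
  annualized by a factor 4, and human-capital production loss.

Registry record sets are pandas DataFrames with the column schemas given by
the ``*_COLUMNS`` constants; ``read_registry``/``write_registry`` round-trip
them as plain CSV files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    ALIVE_STATES,
    DiseaseState,
    CostSpec,
    SchemaError,
    TransitionSpec,
    UtilitySpec,
)

__all__ = [
    "CalibrationError",
    "EmptyCurveError",
    "InsufficientDataError",
    "Registry",
    "IncidenceCurve",
    "TransitionRead",
    "CalibrationResult",
    "cumulative_incidence_competing",
    "cumulative_incidence_all",
    "kaplan_meier_naive",
    "transition_summary",
    "annualize_transition",
    "mean_state_utility",
    "annual_ert_cost",
    "annual_hospital_cost",
    "annual_outpatient_cost",
    "annual_production_loss",
    "calibrate",
    "read_registry",
    "write_registry",
]


class CalibrationError(ValueError):
    """Registry data cannot support the requested estimate."""


class EmptyCurveError(CalibrationError):
    """No episodes start in the requested state."""


class InsufficientDataError(CalibrationError):
    """Fewer than four patients were ever at risk."""


EPISODE_COLUMNS = ("patient_id", "state", "start_age", "end_age", "end_event")
EQ5D_COLUMNS = ("patient_id", "age", "state", "utility", "tariff")
DOSE_COLUMNS = (
    "patient_id",
    "state",
    "episode_start_age",
    "episode_end_age",
    "vials_per_month",
)
PROCEDURE_COLUMNS = ("patient_id", "age", "state", "unit_cost", "count")
OUTPATIENT_COLUMNS = ("patient_id", "state", "quarter_age", "visits", "unit_cost")
WORK_COLUMNS = (
    "patient_id",
    "state",
    "employed",
    "disabled_due_to_gd",
    "hours_per_workday",
    "workdays_per_week",
    "sick_days_per_fortnight",
)

#: end_event value for a transition into ``state``
TRANSITION_PREFIX = "transition_to:"
CENSORED = "censored"
DEATH = "death"

_REGISTRY_FILES = {
    "episodes": EPISODE_COLUMNS,
    "eq5d": EQ5D_COLUMNS,
    "doses": DOSE_COLUMNS,
    "procedures": PROCEDURE_COLUMNS,
    "outpatient": OUTPATIENT_COLUMNS,
    "work": WORK_COLUMNS,
}


@dataclass
class Registry:
    """Patient-level record sets (one DataFrame per concern)."""

    episodes: pd.DataFrame
    eq5d: pd.DataFrame
    doses: pd.DataFrame
    procedures: pd.DataFrame
    outpatient: pd.DataFrame
    work: pd.DataFrame

    def __post_init__(self) -> None:
        for name, columns in _REGISTRY_FILES.items():
            frame = getattr(self, name)
            missing = set(columns) - set(frame.columns)
            if missing:
                raise SchemaError(f"registry {name}: missing columns {sorted(missing)}")

    @classmethod
    def empty(cls) -> "Registry":
        return cls(
            **{
                name: pd.DataFrame(columns=list(cols))
                for name, cols in _REGISTRY_FILES.items()
            }
        )


def read_registry(directory: "Path | str") -> Registry:
    directory = Path(directory)
    frames = {}
    for name in _REGISTRY_FILES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"registry file {path} does not exist")
        frames[name] = pd.read_csv(path)
    return Registry(**frames)


def write_registry(registry: Registry, directory: "Path | str") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _REGISTRY_FILES:
        getattr(registry, name).to_csv(directory / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# competing-risk incidence and the median-time rule
# ---------------------------------------------------------------------------


@dataclass
class IncidenceCurve:
    """Cause-specific cumulative incidence step curve with at-risk counts.

    ``times`` are the distinct observed times since state entry (events and
    censorings); ``cif`` the cumulative incidence of the destination of
    interest at each time, ``event_free`` the overall Kaplan-Meier
    event-free fraction, and ``at_risk`` the number at risk just before
    each time.
    """

    times: np.ndarray
    cif: np.ndarray
    event_free: np.ndarray
    at_risk: np.ndarray
    n_start: int
    cause: str


def _curve_inputs(
    episodes: pd.DataFrame, from_state: DiseaseState
) -> tuple[np.ndarray, np.ndarray]:
    rows = episodes[episodes["state"] == from_state.value]
    if rows.empty:
        raise EmptyCurveError(f"no episodes start in state {from_state}")
    durations = (rows["end_age"] - rows["start_age"]).to_numpy(dtype=float)
    if np.any(durations < 0):
        raise SchemaError("episode end_age before start_age")
    causes = rows["end_event"].to_numpy(dtype=object)
    return durations, causes


def _aalen_johansen(
    durations: np.ndarray, causes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """All-cause KM and per-cause cumulative incidences at distinct times.

    Ties are broken by counting events before censorings: subjects censored
    at time t remain at risk for events at t.
    """
    order = np.argsort(durations, kind="stable")
    durations = durations[order]
    causes = causes[order]
    times = np.unique(durations)
    n = durations.size
    cause_names = sorted({c for c in causes if c != CENSORED})
    at_risk = np.empty(times.size)
    surv = np.empty(times.size)
    cifs = {c: np.zeros(times.size) for c in cause_names}
    s_prev = 1.0
    cum = {c: 0.0 for c in cause_names}
    for j, t in enumerate(times):
        risk = int(np.sum(durations >= t))
        at_risk[j] = risk
        here = durations == t
        d_total = int(np.sum(here & (causes != CENSORED)))
        if risk > 0 and d_total > 0:
            for c in cause_names:
                d_c = int(np.sum(here & (causes == c)))
                if d_c:
                    cum[c] += s_prev * d_c / risk
            s_prev *= 1.0 - d_total / risk
        surv[j] = s_prev
        for c in cause_names:
            cifs[c][j] = cum[c]
    return times, at_risk, cifs, surv


def cumulative_incidence_all(
    episodes: pd.DataFrame, from_state: DiseaseState
) -> dict[str, IncidenceCurve]:
    """Cumulative incidence curves for every competing destination at once."""
    durations, causes = _curve_inputs(episodes, from_state)
    times, at_risk, cifs, surv = _aalen_johansen(durations, causes)
    return {
        cause: IncidenceCurve(times, cif, surv, at_risk, durations.size, cause)
        for cause, cif in cifs.items()
    }


def cumulative_incidence_competing(
    episodes: pd.DataFrame,
    from_state: DiseaseState,
    to_state: DiseaseState,
) -> IncidenceCurve:
    """Cumulative incidence of one transition, correcting for competing risks."""
    durations, causes = _curve_inputs(episodes, from_state)
    times, at_risk, cifs, surv = _aalen_johansen(durations, causes)
    cause = TRANSITION_PREFIX + to_state.value
    cif = cifs.get(cause, np.zeros(times.size))
    return IncidenceCurve(times, cif, surv, at_risk, durations.size, cause)


def kaplan_meier_naive(
    episodes: pd.DataFrame, from_state: DiseaseState, to_state: DiseaseState
) -> IncidenceCurve:
    """1 - KM treating competing events as censorings (sensitivity only).

    Overstates incidence when competing risks are present; provided for
    comparison with the competing-risk corrected estimate.
    """
    durations, causes = _curve_inputs(episodes, from_state)
    cause = TRANSITION_PREFIX + to_state.value
    recoded = np.where(causes == cause, causes, CENSORED)
    times, at_risk, cifs, surv = _aalen_johansen(durations, recoded)
    cif = cifs.get(cause, np.zeros(times.size))
    return IncidenceCurve(times, cif, surv, at_risk, durations.size, cause)


@dataclass(frozen=True)
class TransitionRead:
    """Reading point of an incidence curve: cumulative proportion and time."""

    p_cum: float
    t_ref: float
    rule: str  # "median" | "at_risk_4"


def transition_summary(
    curve: IncidenceCurve, min_at_risk: int = 4
) -> TransitionRead:
    """Read a cumulative proportion and reference time off an incidence curve.

    If the curve reaches 0.5 the reading is (0.5, the time at which it
    does); a step jumping over 0.5 is read at the linearly interpolated
    crossing time.  Otherwise the curve is read at the last observed time
    with at least ``min_at_risk`` patients still at risk.
    """
    if curve.times.size == 0:
        raise EmptyCurveError("curve has no observed times")
    if curve.n_start < min_at_risk or not np.any(curve.at_risk >= min_at_risk):
        raise InsufficientDataError(
            f"fewer than {min_at_risk} patients ever at risk"
        )
    reached = np.nonzero(curve.cif >= 0.5)[0]
    if reached.size:
        j = int(reached[0])
        t_hi, c_hi = float(curve.times[j]), float(curve.cif[j])
        if c_hi == 0.5:
            return TransitionRead(0.5, t_hi, "median")
        t_lo, c_lo = (0.0, 0.0) if j == 0 else (
            float(curve.times[j - 1]),
            float(curve.cif[j - 1]),
        )
        t_star = t_lo + (0.5 - c_lo) / (c_hi - c_lo) * (t_hi - t_lo)
        return TransitionRead(0.5, t_star, "median")
    ok = np.nonzero(curve.at_risk >= min_at_risk)[0]
    j = int(ok[-1])
    return TransitionRead(float(curve.cif[j]), float(curve.times[j]), "at_risk_4")


def annualize_transition(p_cum: float, t_ref: float) -> float:
    """Markov correction: constant annual probability with the same
    cumulative incidence over ``t_ref`` years, p = 1 - (1 - P)^(1/t)."""
    if t_ref <= 0:
        raise CalibrationError(f"reference time {t_ref} must be positive")
    if not 0.0 <= p_cum <= 1.0:
        raise CalibrationError(f"cumulative proportion {p_cum} outside [0, 1]")
    if p_cum == 1.0:
        warnings.warn("cumulative proportion 1 implies instantaneous transition")
        return 1.0
    return 1.0 - (1.0 - p_cum) ** (1.0 / t_ref)


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def _bca_interval(
    per_patient: np.ndarray, reps: int, rng: "np.random.Generator | None"
) -> tuple[float | None, float | None]:
    if per_patient.size < 2 or reps < 1:
        return None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.bootstrap(
                (per_patient,),
                np.mean,
                method="BCa",
                n_resamples=reps,
                confidence_level=0.95,
                batch=1000,  # bounds resample/jackknife memory at large n
                rng=rng,
            )
        except Exception:
            return None, None
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return None, None
    return lo, hi


def mean_state_utility(
    records: pd.DataFrame,
    state: DiseaseState,
    bootstrap_reps: int = 2000,
    rng: "np.random.Generator | None" = None,
) -> UtilitySpec:
    """Two-stage mean utility for one state with BCa bootstrap CI.

    Utilities are averaged per patient first, then over patients, so a
    patient with many observations weighs no more than one with few.  The
    CI resamples patients; with a single patient it is flagged unavailable
    (returned as None limits).
    """
    rows = records[records["state"] == state.value]
    if rows.empty:
        raise CalibrationError(f"no utility observations in state {state}")
    tariffs = rows["tariff"].unique()
    if tariffs.size != 1:
        raise SchemaError(f"mixed tariffs {tariffs} in utility records")
    per_patient = rows.groupby("patient_id")["utility"].mean().to_numpy()
    mean = float(per_patient.mean())
    lcl, ucl = _bca_interval(per_patient, bootstrap_reps, rng)
    if lcl is not None and not lcl <= mean <= ucl:
        lcl, ucl = None, None  # degenerate resample distribution
    return UtilitySpec(state=state, mean_u=mean, lcl=lcl, ucl=ucl, tariff=str(tariffs[0]))


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------


def annual_ert_cost(
    records: pd.DataFrame, state: DiseaseState, vial_unit_cost: float
) -> tuple[float, float]:
    """Mean annual ERT vial use and medication cost in one state.

    Monthly vial counts are averaged per patient weighted by dose-episode
    length, averaged over patients, then multiplied by 12 and the vial
    unit cost.
    """
    if vial_unit_cost <= 0:
        raise CalibrationError("vial unit cost must be positive")
    rows = records[records["state"] == state.value].copy()
    if rows.empty:
        raise CalibrationError(f"no dose records in state {state}")
    rows["length"] = rows["episode_end_age"] - rows["episode_start_age"]
    if np.any(rows["length"] < 0):
        raise SchemaError("dose episode with negative length")
    means = []
    for pid, grp in rows.groupby("patient_id"):
        total = grp["length"].sum()
        if total <= 0:
            warnings.warn(f"patient {pid}: zero total dose-episode length, excluded")
            continue
        means.append(float((grp["vials_per_month"] * grp["length"]).sum() / total))
    if not means:
        raise CalibrationError(f"no usable dose episodes in state {state}")
    vials_per_year = 12.0 * float(np.mean(means))
    return vials_per_year, vials_per_year * vial_unit_cost


def _state_followup_years(
    episodes: pd.DataFrame, state: DiseaseState
) -> pd.Series:
    rows = episodes[episodes["state"] == state.value]
    if rows.empty:
        raise CalibrationError(f"no episodes in state {state}")
    years = (rows["end_age"] - rows["start_age"]).groupby(rows["patient_id"]).sum()
    return years


def annual_hospital_cost(
    records: pd.DataFrame,
    episodes: pd.DataFrame,
    state: DiseaseState,
    bootstrap_reps: int = 2000,
    rng: "np.random.Generator | None" = None,
) -> CostSpec:
    """Mean yearly hospital procedure cost per patient in one state.

    Product sum of procedures and unit costs per patient, divided by the
    patient's years of follow-up in the state, then averaged over patients.
    """
    years = _state_followup_years(episodes, state)
    rows = records[records["state"] == state.value]
    totals = (rows["unit_cost"] * rows["count"]).groupby(rows["patient_id"]).sum()
    per_patient = []
    excluded = []
    for pid, yrs in years.items():
        if yrs <= 0:
            excluded.append(pid)
            continue
        per_patient.append(float(totals.get(pid, 0.0)) / float(yrs))
    if excluded:
        warnings.warn(
            f"{len(excluded)} patient(s) with zero follow-up in {state} excluded"
        )
    if not per_patient:
        raise CalibrationError(f"no usable follow-up in state {state}")
    per_patient = np.asarray(per_patient)
    lcl, ucl = _bca_interval(per_patient, bootstrap_reps, rng)
    mean = float(per_patient.mean())
    if lcl is not None and not lcl <= mean <= ucl:
        lcl, ucl = None, None
    return CostSpec(state=state, component="hospital", mean_annual_cost=mean, lcl=lcl, ucl=ucl)


def annual_outpatient_cost(
    quarterly_records: pd.DataFrame,
    state: DiseaseState,
    bootstrap_reps: int = 2000,
    rng: "np.random.Generator | None" = None,
) -> CostSpec:
    """Mean yearly out-of-hospital cost: per-patient mean quarterly cost x 4,
    then averaged over patients."""
    rows = quarterly_records[quarterly_records["state"] == state.value]
    if rows.empty:
        raise CalibrationError(f"no outpatient records in state {state}")
    quarter_cost = rows["visits"] * rows["unit_cost"]
    per_patient = 4.0 * quarter_cost.groupby(rows["patient_id"]).mean()
    values = per_patient.to_numpy(dtype=float)
    lcl, ucl = _bca_interval(values, bootstrap_reps, rng)
    mean = float(values.mean())
    if lcl is not None and not lcl <= mean <= ucl:
        lcl, ucl = None, None
    return CostSpec(
        state=state, component="out_of_hospital", mean_annual_cost=mean, lcl=lcl, ucl=ucl
    )


def annual_production_loss(
    records: pd.DataFrame,
    state: DiseaseState,
    hourly_cost: float = 30.0,
    bootstrap_reps: int = 2000,
    rng: "np.random.Generator | None" = None,
) -> CostSpec:
    """Mean yearly production loss per patient (human capital method).

    Employed patients lose sick days x 26 x the overall mean working hours
    per day; patients with permanent GD-related work disability lose a
    full-time equivalent (52 x overall mean workdays/week x overall mean
    hours/day); patients without paid work for other reasons lose nothing.
    """
    if hourly_cost <= 0:
        raise CalibrationError("hourly production cost must be positive")
    employed_all = records[records["employed"].astype(bool)]
    if employed_all.empty:
        mean_hours = 0.0
        mean_days = 0.0
    else:
        mean_hours = float(employed_all["hours_per_workday"].mean())
        mean_days = float(employed_all["workdays_per_week"].mean())
    rows = records[records["state"] == state.value]
    if rows.empty:
        raise CalibrationError(f"no work records in state {state}")
    disabled = rows["disabled_due_to_gd"].to_numpy(dtype=bool)
    employed = rows["employed"].to_numpy(dtype=bool)
    sick = rows["sick_days_per_fortnight"].to_numpy(dtype=float)
    if np.any((sick < 0) | (sick > 14)):
        raise SchemaError("sick days per fortnight outside [0, 14]")
    values = np.where(
        disabled,
        52.0 * mean_days * mean_hours * hourly_cost,
        np.where(employed, sick * 26.0 * mean_hours * hourly_cost, 0.0),
    ).astype(float)
    lcl, ucl = _bca_interval(values, bootstrap_reps, rng)
    mean = float(values.mean())
    if lcl is not None and not lcl <= mean <= ucl:
        lcl, ucl = None, None
    return CostSpec(
        state=state, component="production_loss", mean_annual_cost=mean, lcl=lcl, ucl=ucl
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Everything calibration recovers, in StrategySpec-compatible form."""

    transitions: tuple[TransitionSpec, ...] = ()
    utilities: tuple[UtilitySpec, ...] = ()
    costs: tuple[CostSpec, ...] = ()
    ert_dosing: dict[DiseaseState, float] = field(default_factory=dict)
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    missing: tuple[str, ...] = ()

    def transition_prob(self, frm: DiseaseState, to: DiseaseState) -> "float | None":
        for tr in self.transitions:
            if tr.from_state is frm and tr.to_state is to:
                return tr.mean_p
        return None

    def utility(self, state: DiseaseState) -> "float | None":
        for u in self.utilities:
            if u.state is state:
                return u.mean_u
        return None

    def cost(self, state: DiseaseState, component: str) -> "float | None":
        for c in self.costs:
            if c.state is state and c.component == component:
                return c.mean_annual_cost
        return None


def calibrate(
    registry: Registry,
    strategy_label: str,
    vial_unit_cost: float = 1985.0,
    hourly_production_cost: float = 30.0,
    bootstrap_reps: int = 2000,
    rng: "np.random.Generator | None" = None,
) -> CalibrationResult:
    """Run every estimation step over a registry for one strategy's data.

    States or transitions without data are reported in ``missing`` rather
    than silently set to zero.
    """
    is_ert = strategy_label != "no_ert"
    transitions: list[TransitionSpec] = []
    utilities: list[UtilitySpec] = []
    costs: list[CostSpec] = []
    dosing: dict[DiseaseState, float] = {}
    missing: list[str] = []
    diag_rows: list[dict] = []

    episodes = registry.episodes
    for from_state in ALIVE_STATES:
        try:
            curves = cumulative_incidence_all(episodes, from_state)
        except EmptyCurveError:
            missing.append(f"episodes:{from_state.value}")
            continue
        for cause, curve in sorted(curves.items()):
            if not cause.startswith(TRANSITION_PREFIX):
                continue  # death is a competing risk, not a fitted transition
            to_state = DiseaseState(cause.removeprefix(TRANSITION_PREFIX))
            try:
                read = transition_summary(curve)
            except InsufficientDataError:
                missing.append(f"transition:{from_state.value}->{to_state.value}")
                continue
            p = annualize_transition(read.p_cum, read.t_ref)
            transitions.append(
                TransitionSpec(
                    from_state=from_state,
                    to_state=to_state,
                    mean_p=p,
                    source_label=f"calibrated:{read.rule}",
                )
            )
            diag_rows.append(
                {
                    "estimate": f"transition:{from_state.value}->{to_state.value}",
                    "n": curve.n_start,
                    "rule": read.rule,
                    "p_cum": read.p_cum,
                    "t_ref": read.t_ref,
                }
            )

    for state in ALIVE_STATES:
        rows = registry.eq5d[registry.eq5d["state"] == state.value]
        if rows.empty:
            missing.append(f"utility:{state.value}")
        else:
            spec = mean_state_utility(registry.eq5d, state, bootstrap_reps, rng)
            utilities.append(spec)
            diag_rows.append(
                {
                    "estimate": f"utility:{state.value}",
                    "n": rows["patient_id"].nunique(),
                }
            )

        try:
            costs.append(
                annual_hospital_cost(
                    registry.procedures, registry.episodes, state, bootstrap_reps, rng
                )
            )
            diag_rows.append(
                {
                    "estimate": f"hospital:{state.value}",
                    "n": _state_followup_years(registry.episodes, state).size,
                }
            )
        except CalibrationError:
            missing.append(f"hospital:{state.value}")
        try:
            costs.append(
                annual_outpatient_cost(registry.outpatient, state, bootstrap_reps, rng)
            )
        except CalibrationError:
            missing.append(f"out_of_hospital:{state.value}")
        try:
            costs.append(
                annual_production_loss(
                    registry.work, state, hourly_production_cost, bootstrap_reps, rng
                )
            )
        except CalibrationError:
            missing.append(f"production_loss:{state.value}")

        if is_ert and state is not DiseaseState.ASYMPTOMATIC:
            try:
                vials, cost = annual_ert_cost(registry.doses, state, vial_unit_cost)
                dosing[state] = vials
                costs.append(
                    CostSpec(state=state, component="ert", mean_annual_cost=cost)
                )
            except CalibrationError:
                missing.append(f"ert:{state.value}")

    return CalibrationResult(
        transitions=tuple(transitions),
        utilities=tuple(utilities),
        costs=tuple(costs),
        ert_dosing=dosing,
        diagnostics=pd.DataFrame(diag_rows),
        missing=tuple(missing),
    )
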